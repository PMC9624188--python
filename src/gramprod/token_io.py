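"""Reading and writing token lists and report tables.

The exchange format is deliberately minimal: one usage event per line, the
lemma and its marker joined by a single underscore (``com_o`` = lemma *com*
with first-singular ``-o``).  An optional tab-separated second column carries
a transcript index so a corpus can later be split into chronological halves.
Blank lines and ``#`` comments are skipped.  Tokens form a multiset: repeated
identical lines are distinct usage events and are never deduplicated.
"""

from __future__ import annotations

import csv
import os
from dataclasses import dataclass, field
from typing import Iterable, NamedTuple, Sequence, TYPE_CHECKING

from .errors import EmptySampleError, TokenFormatError

if TYPE_CHECKING:  # pragma: no cover
    from .inference import BootstrapCI
    from .productivity import ProductivityResult

__all__ = [
    "Token",
    "TokenSample",
    "read_token_file",
    "write_token_file",
    "write_report",
]


class Token(NamedTuple):
    """One usage event: a lemma paired with a surface marker."""

    lemma: str
    marker: str
    transcript_index: int | None = None


@dataclass(frozen=True)
class TokenSample:
    """An ordered multiset of tokens with a speaker/occasion label."""

    tokens: tuple[Token, ...]
    label: str = ""
    lemma_set: frozenset[str] = field(init=False, compare=False)

    def __post_init__(self) -> None:
        object.__setattr__(self, "lemma_set", frozenset(t.lemma for t in self.tokens))

    @property
    def n_tokens(self) -> int:
        return len(self.tokens)

    @property
    def n_lemmas(self) -> int:
        return len(self.lemma_set)

    def __len__(self) -> int:
        return len(self.tokens)

    def __iter__(self):
        return iter(self.tokens)


def _parse_record(record: str, line_no: int, case_fold_lemmas: bool) -> tuple[str, str]:
    parts = record.split("_")
    if len(parts) != 2 or not parts[0] or not parts[1]:
        raise TokenFormatError(
            f"line {line_no}: malformed token {record!r} "
            "(expected exactly two non-empty fields joined by one underscore)",
            line_no=line_no,
            text=record,
        )
    lemma, marker = parts
    if case_fold_lemmas:
        lemma = lemma.casefold()
    return lemma, marker


def read_token_file(
    path: str | os.PathLike[str],
    dialect: str = "line",
    case_fold_lemmas: bool = True,
    label: str | None = None,
) -> TokenSample:
    """Parse a token-list file into a :class:`TokenSample`.

    ``dialect="line"`` (canonical): one ``lemma_marker`` record per line with
    an optional tab-separated transcript index.  ``dialect="whitespace"``
    (permissive): records separated by any whitespace, no transcript column.
    Lemmas are casefolded by default because transcript exports capitalize
    sentence-initial words; pass ``case_fold_lemmas=False`` to keep case.
    """
    if dialect not in ("line", "whitespace"):
        raise ValueError(f"unknown dialect {dialect!r}")
    tokens: list[Token] = []
    with open(path, encoding="utf-8") as fh:
        for line_no, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            if dialect == "whitespace":
                for rec in line.split():
                    lemma, marker = _parse_record(rec, line_no, case_fold_lemmas)
                    tokens.append(Token(lemma, marker))
                continue
            cols = line.split("\t")
            if len(cols) > 2:
                raise TokenFormatError(
                    f"line {line_no}: too many columns ({len(cols)}) in {line!r}",
                    line_no=line_no,
                    text=line,
                )
            lemma, marker = _parse_record(cols[0].strip(), line_no, case_fold_lemmas)
            idx: int | None = None
            if len(cols) == 2:
                try:
                    idx = int(cols[1].strip())
                except ValueError:
                    raise TokenFormatError(
                        f"line {line_no}: transcript index {cols[1]!r} is not an integer",
                        line_no=line_no,
                        text=line,
                    ) from None
                if idx < 0:
                    raise TokenFormatError(
                        f"line {line_no}: transcript index must be non-negative",
                        line_no=line_no,
                        text=line,
                    )
            tokens.append(Token(lemma, marker, idx))
    if not tokens:
        raise EmptySampleError(f"no tokens in {os.fspath(path)!r}")
    return TokenSample(tuple(tokens), label=label if label is not None else str(path))


def write_token_file(sample: TokenSample, path: str | os.PathLike[str]) -> None:
    """Write a sample back to the canonical one-record-per-line format.

    Tokens keep their order; tokens carrying a transcript index are written
    as two tab-separated columns.  Round trips with :func:`read_token_file`
    are lossless (up to lemma casefolding applied at read time).
    """
    if sample.n_tokens == 0:
        raise EmptySampleError("refusing to write an empty token sample")
    with open(path, "w", encoding="utf-8") as fh:
        for t in sample:
            rec = f"{t.lemma}_{t.marker}"
            if t.transcript_index is not None:
                rec = f"{rec}\t{t.transcript_index}"
            fh.write(rec + "\n")


_REPORT_COLUMNS = ("Control", "Sample", "CRE", "sd", "Tokens", "Verbs", "TRI_pct")
_CI_COLUMNS = ("method", "level", "low", "high", "R", "observed_mean")


def write_report(
    rows: Sequence["ProductivityResult"],
    ci: "BootstrapCI | Iterable[BootstrapCI] | None",
    path: str | os.PathLike[str],
) -> None:
    """Write the descriptive report table as CSV, CI summary appended.

    Columns mirror the standard layout of productivity tables — control
    condition, sample label, mean creativity ("inflections per verb") with its
    across-lemma sd, token and lemma-type counts, and triteness percent — with
    CRE/sd/TRI rounded to two decimals.  Confidence intervals, when given,
    follow the data block under their own header.
    """
    if not rows:
        raise EmptySampleError("report needs at least one row")
    cis: list[BootstrapCI]
    if ci is None:
        cis = []
    elif hasattr(ci, "method"):
        cis = [ci]  # type: ignore[list-item]
    else:
        cis = list(ci)  # type: ignore[arg-type]
    with open(path, "w", encoding="utf-8", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(_REPORT_COLUMNS)
        for r in rows:
            w.writerow(
                [
                    r.control,
                    r.label,
                    f"{r.cre_mean:.2f}",
                    f"{r.cre_sd:.2f}",
                    r.n_tokens,
                    r.n_lemmas,
                    f"{r.tri_pct:.2f}",
                ]
            )
        if cis:
            w.writerow([])
            w.writerow(_CI_COLUMNS)
            for c in cis:
                w.writerow(
                    [
                        c.method,
                        f"{c.level:g}",
                        f"{c.low:.6f}",
                        f"{c.high:.6f}",
                        c.n_replicates,
                        f"{c.observed_mean:.6f}",
                    ]
                )
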
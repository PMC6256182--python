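"""Reading and writing frequency lexicons, lexicon snapshots, and measures tables.

All on-disk formats are UTF-8 text with LF line endings:

* frequency lexicon — TSV with header ``type<TAB>frequency``;
* lexicon snapshot — one word type per line, preceded by a sidecar header
  ``# participant=<id> grade=<label> size=<n>``;
* measures table — TSV, one row per (participant, grade).

Word types are NFC-normalized on read so composed and decomposed umlauts
compare equal downstream (the Levenshtein distance must see one symbol per
grapheme). Entry order is preserved exactly as read: sampling tie-breaking
depends on it.
"""

from __future__ import annotations

import logging
import unicodedata
from dataclasses import dataclass, field
from pathlib import Path
from typing import TYPE_CHECKING, Iterator, Mapping, Sequence

import numpy as np
import pandas as pd

if TYPE_CHECKING:  # pragma: no cover
    from .graph_metrics import NetworkMeasures

logger = logging.getLogger(__name__)

LEXICON_HEADER = "type\tfrequency"

#: Column order of the measures table.
MEASURES_COLUMNS = (
    "participant",
    "grade",
    "lexicon_size",
    "n",
    "mean_degree",
    "L",
    "D",
    "C",
    "hermits",
    "hermit_proportion",
)


class LexiconFormatError(ValueError):
    """Raised when a lexicon file violates the TSV contract."""


@dataclass(frozen=True)
class FrequencyLexicon:
    """An ordered frequency lexicon: word types with positive token frequencies.

    This is the learning environment of the growth simulation.  Invariants:
    types are unique (after NFC normalization), every frequency is > 0, and
    entry order is significant.
    """

    words: tuple[str, ...]
    frequencies: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        freqs = np.asarray(self.frequencies, dtype=float)
        object.__setattr__(self, "frequencies", freqs)
        if len(self.words) != len(freqs):
            raise ValueError("words and frequencies must have equal length")
        if len(set(self.words)) != len(self.words):
            raise ValueError("word types must be unique")
        if len(freqs) and not np.all(freqs > 0):
            raise ValueError("all frequencies must be positive")

    def __len__(self) -> int:
        return len(self.words)

    def __iter__(self) -> Iterator[tuple[str, float]]:
        return zip(self.words, self.frequencies.tolist())

    @property
    def entries(self) -> list[tuple[str, float]]:
        return list(self)

    def frequency_of(self) -> dict[str, float]:
        """Word type -> frequency lookup table."""
        return dict(zip(self.words, self.frequencies.tolist()))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"type": self.words, "frequency": self.frequencies})


def read_frequency_lexicon(path: str | Path) -> FrequencyLexicon:
    """Read a frequency lexicon from a UTF-8 TSV file.

    The header row must be exactly ``type<TAB>frequency``.  Word types are
    NFC-normalized; duplicates arising from normalization are merged by
    summing their frequencies (with a logged warning).  A non-positive or
    non-numeric frequency raises :class:`ValueError` naming the line.
    """
    path = Path(path)
    words: list[str] = []
    freqs: list[float] = []
    index: dict[str, int] = {}
    with path.open("r", encoding="utf-8", newline="") as fh:
        header = fh.readline().rstrip("\r\n")
        if header != LEXICON_HEADER:
            raise LexiconFormatError(
                f"{path}: expected header {LEXICON_HEADER!r}, got {header!r}"
            )
        for lineno, raw in enumerate(fh, start=2):
            line = raw.rstrip("\r\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise LexiconFormatError(
                    f"{path}:{lineno}: expected 2 tab-separated fields, got {len(parts)}"
                )
            word = unicodedata.normalize("NFC", parts[0])
            try:
                freq = float(parts[1])
            except ValueError:
                raise ValueError(
                    f"{path}:{lineno}: non-numeric frequency {parts[1]!r}"
                ) from None
            if not np.isfinite(freq) or freq <= 0:
                raise ValueError(f"{path}:{lineno}: non-positive frequency {freq!r}")
            if word in index:
                logger.warning(
                    "%s:%d: duplicate type %r after NFC normalization; merging frequencies",
                    path, lineno, word,
                )
                freqs[index[word]] += freq
            else:
                index[word] = len(words)
                words.append(word)
                freqs.append(freq)
    return FrequencyLexicon(tuple(words), np.asarray(freqs, dtype=float))


def write_frequency_lexicon(lexicon: FrequencyLexicon, path: str | Path) -> None:
    """Write a frequency lexicon in the TSV contract format."""
    path = Path(path)
    with path.open("w", encoding="utf-8", newline="\n") as fh:
        fh.write(LEXICON_HEADER + "\n")
        for word, freq in lexicon:
            fh.write(f"{word}\t{freq:.10g}\n")


def write_lexicon_snapshot(
    types: Sequence[str] | set[str],
    path: str | Path,
    *,
    participant: int,
    grade: str,
) -> None:
    """Write one virtual lexicon: sidecar header, then one type per line (sorted)."""
    ordered = sorted(types)
    path = Path(path)
    with path.open("w", encoding="utf-8", newline="\n") as fh:
        fh.write(f"# participant={participant} grade={grade} size={len(ordered)}\n")
        for word in ordered:
            fh.write(word + "\n")


def read_lexicon_snapshot(path: str | Path) -> tuple[int, str, list[str]]:
    """Read a snapshot; returns (participant_id, grade_label, types)."""
    path = Path(path)
    with path.open("r", encoding="utf-8", newline="") as fh:
        header = fh.readline().rstrip("\r\n")
        if not header.startswith("# "):
            raise LexiconFormatError(f"{path}: missing snapshot sidecar header")
        meta = dict(item.split("=", 1) for item in header[2:].split())
        try:
            participant = int(meta["participant"])
            grade = meta["grade"]
            size = int(meta["size"])
        except (KeyError, ValueError) as exc:
            raise LexiconFormatError(f"{path}: malformed sidecar header") from exc
        types = [
            unicodedata.normalize("NFC", line.rstrip("\r\n"))
            for line in fh
            if line.strip()
        ]
    if len(types) != size:
        raise LexiconFormatError(
            f"{path}: header says size={size} but found {len(types)} types"
        )
    return participant, grade, types


def _fmt(value: float | int | None) -> str:
    if value is None:
        return "NA"
    if isinstance(value, (int, np.integer)):
        return str(int(value))
    if np.isnan(value):
        return "NA"
    return format(float(value), ".6g")


def write_measures_table(
    records: Mapping[tuple[int, str], "NetworkMeasures"],
    path: str | Path,
) -> None:
    """Write per-participant, per-grade network measures as a TSV.

    Rows are sorted by (participant, grade); floats are printed at 6
    significant digits.  Raises :class:`ValueError` on an empty mapping.
    """
    if not records:
        raise ValueError("no measures records to write")
    path = Path(path)
    with path.open("w", encoding="utf-8", newline="\n") as fh:
        fh.write("\t".join(MEASURES_COLUMNS) + "\n")
        for (participant, grade) in sorted(records):
            m = records[(participant, grade)]
            row = [
                str(participant),
                grade,
                str(m.lexicon_size),
                str(m.n),
                _fmt(m.mean_degree),
                _fmt(m.avg_path_length),
                _fmt(m.diameter),
                _fmt(m.clustering),
                str(m.hermit_count),
                _fmt(m.hermit_proportion),
            ]
            fh.write("\t".join(row) + "\n")


def read_measures_table(path: str | Path) -> pd.DataFrame:
    """Read a measures table back into a DataFrame (grade kept as string)."""
    return pd.read_csv(
        path, sep="\t", dtype={"grade": str, "participant": int}, na_values=["NA"]
    )
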
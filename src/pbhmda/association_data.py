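"""Microbe-disease association tables.

The central container is :class:`AssociationMatrix`: a binary ``nm x nd``
adjacency matrix ``Y`` over ``nm`` microbes (rows) and ``nd`` diseases
(columns), with ``Y[i, j] = 1`` exactly when microbe *i* has a curated
association with disease *j*.  Name registries keep first-appearance order;
all indexing is 0-based internally and every user-facing artifact speaks in
names, never indices.

Input files are HMDAD-style two-column association lists (tab- or
comma-separated, one ``microbe <sep> disease`` pair per line, ``#`` comments
skipped).  Names are matched case-sensitively after trimming surrounding
whitespace; no taxonomic normalisation is attempted.
"""

from __future__ import annotations

import dataclasses
import os
from functools import cached_property
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "AssociationMatrix",
    "ParseError",
    "load_associations",
    "parse_associations",
    "write_associations",
    "write_score_table",
]


class ParseError(ValueError):
    """Raised when an association file cannot be parsed."""


#: Lower-cased field names recognised as a header line.
_HEADER_TOKENS = {
    "microbe", "microbe_name", "microbe_id", "microbes",
    "disease", "disease_name", "disease_id", "diseases",
    "score", "rank",
}


@dataclasses.dataclass(frozen=True)
class AssociationMatrix:
    """Binary microbe-disease adjacency matrix with name registries.

    Parameters
    ----------
    values
        ``(nm, nd)`` array of 0/1 entries; stored as ``int8``.
    microbe_names, disease_names
        Unique row / column names, in registry order.
    """

    values: np.ndarray
    microbe_names: tuple[str, ...]
    disease_names: tuple[str, ...]

    def __post_init__(self) -> None:
        v = np.asarray(self.values)
        if v.ndim != 2:
            raise ValueError(f"values must be a 2-d matrix, got ndim={v.ndim}")
        if v.size and not np.isin(v, (0, 1)).all():
            raise ValueError("association matrix entries must be exactly 0 or 1")
        mn = tuple(str(n) for n in self.microbe_names)
        dn = tuple(str(n) for n in self.disease_names)
        if len(mn) < 1 or len(dn) < 1:
            raise ValueError("need at least one microbe and one disease")
        if v.shape != (len(mn), len(dn)):
            raise ValueError(
                f"shape {v.shape} inconsistent with {len(mn)} microbes x {len(dn)} diseases"
            )
        if len(set(mn)) != len(mn):
            raise ValueError("duplicate microbe names in registry")
        if len(set(dn)) != len(dn):
            raise ValueError("duplicate disease names in registry")
        object.__setattr__(self, "values", np.ascontiguousarray(v, dtype=np.int8))
        object.__setattr__(self, "microbe_names", mn)
        object.__setattr__(self, "disease_names", dn)

    # -- basic views -------------------------------------------------------

    @property
    def n_microbes(self) -> int:
        return self.values.shape[0]

    @property
    def n_diseases(self) -> int:
        return self.values.shape[1]

    @property
    def n_associations(self) -> int:
        """Number of known (Y=1) pairs."""
        return int(self.values.sum())

    @cached_property
    def microbe_index(self) -> dict[str, int]:
        return {n: i for i, n in enumerate(self.microbe_names)}

    @cached_property
    def disease_index(self) -> dict[str, int]:
        return {n: j for j, n in enumerate(self.disease_names)}

    def known_pairs(self) -> list[tuple[int, int]]:
        """Row-major list of (microbe index, disease index) with Y=1."""
        rows, cols = np.nonzero(self.values)
        return list(zip(rows.tolist(), cols.tolist()))

    def without(self, pairs: Iterable[tuple[int, int]]) -> "AssociationMatrix":
        """Copy with the given (i, j) entries set to 0 (hold-out helper)."""
        v = self.values.copy()
        for i, j in pairs:
            v[i, j] = 0
        return AssociationMatrix(v, self.microbe_names, self.disease_names)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, AssociationMatrix):
            return NotImplemented
        return (
            self.microbe_names == other.microbe_names
            and self.disease_names == other.disease_names
            and np.array_equal(self.values, other.values)
        )

    __hash__ = None  # type: ignore[assignment]


# -- parsing ---------------------------------------------------------------


def _split_fields(line: str, sep: str | None) -> list[str]:
    if sep is not None:
        parts = line.split(sep)
    elif "\t" in line:
        parts = line.split("\t")
    elif "," in line:
        parts = line.split(",")
    else:
        parts = line.split()
    return [p.strip() for p in parts]


def parse_associations(
    lines: Iterable[str],
    sep: str | None = None,
    dedupe: bool = True,
    header: bool | None = None,
    source: str = "<stream>",
) -> AssociationMatrix:
    """Parse association lines into an :class:`AssociationMatrix`.

    ``sep=None`` auto-detects tab, then comma, then any whitespace.  With
    ``header=None`` the first data line is dropped when both of its fields
    look like column titles (``microbe``/``disease`` variants); pass
    ``header=True``/``False`` to force.  ``dedupe=False`` turns repeated
    pairs into a :class:`ParseError` instead of collapsing them to one 1.
    """
    pairs: list[tuple[str, str]] = []
    seen: set[tuple[str, str]] = set()
    first_data_line = True
    for lineno, raw in enumerate(lines, start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        fields = _split_fields(line, sep)
        if len(fields) != 2 or not all(fields):
            raise ParseError(
                f"{source}: line {lineno}: expected 2 fields, got {len(fields)}: {line!r}"
            )
        if first_data_line:
            first_data_line = False
            looks_like_header = all(f.lower() in _HEADER_TOKENS for f in fields)
            if header is True or (header is None and looks_like_header):
                continue
        m, d = fields
        key = (m, d)
        if key in seen:
            if not dedupe:
                raise ParseError(f"{source}: line {lineno}: duplicate pair {key!r}")
            continue
        seen.add(key)
        pairs.append(key)
    if not pairs:
        raise ParseError(f"{source}: no association pairs found")

    midx: dict[str, int] = {}
    didx: dict[str, int] = {}
    for m, d in pairs:
        midx.setdefault(m, len(midx))
        didx.setdefault(d, len(didx))
    Y = np.zeros((len(midx), len(didx)), dtype=np.int8)
    for m, d in pairs:
        Y[midx[m], didx[d]] = 1
    return AssociationMatrix(Y, tuple(midx), tuple(didx))


def load_associations(
    path: str | os.PathLike[str],
    sep: str | None = None,
    dedupe: bool = True,
    header: bool | None = None,
) -> AssociationMatrix:
    """Load a two-column association list from ``path``."""
    with open(path, "r", encoding="utf-8") as fh:
        return parse_associations(fh, sep=sep, dedupe=dedupe, header=header,
                                  source=os.fspath(path))


# -- writing ---------------------------------------------------------------


def write_associations(
    matrix: AssociationMatrix, path: str | os.PathLike[str], sep: str = "\t"
) -> None:
    """Write the known pairs back out as a two-column list (round-trippable)."""
    lines = [
        f"{matrix.microbe_names[i]}{sep}{matrix.disease_names[j]}"
        for i, j in matrix.known_pairs()
    ]
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write("\n".join(lines) + "\n")


def _echo_lines(config_echo: dict | None) -> list[str]:
    if not config_echo:
        return []
    return [f"# {k} = {config_echo[k]}" for k in sorted(config_echo)]


def write_score_table(
    scores,
    path: str | os.PathLike[str],
    per_disease_rank: bool = True,
    config_echo: dict | None = None,
) -> None:
    """Write a long-format (disease, microbe, score, rank) prediction table.

    With ``per_disease_rank`` ranks restart at 1 within each disease (sorted
    by descending score); otherwise a single global ranking is emitted.  Ties
    are broken by (disease name, microbe name) ascending so output is
    deterministic across runs and platforms.

    Parameters
    ----------
    scores
        A :class:`~pbhmda.path_scoring.ScoreMatrix` (anything exposing
        ``values``, ``microbe_names`` and ``disease_names``).
    config_echo
        Optional parameter mapping echoed as leading ``#`` comment lines.
    """
    vals = np.asarray(scores.values, dtype=float)
    if not np.isfinite(vals).all():
        raise ValueError("scores must be finite")
    rows = [
        (d, m, float(vals[i, j]))
        for j, d in enumerate(scores.disease_names)
        for i, m in enumerate(scores.microbe_names)
    ]
    lines = _echo_lines(config_echo)
    lines.append("disease\tmicrobe\tscore\trank")
    if per_disease_rank:
        rows.sort(key=lambda r: (r[0], -r[2], r[1]))
        rank = 0
        current = None
        for d, m, s in rows:
            rank = rank + 1 if d == current else 1
            current = d
            lines.append(f"{d}\t{m}\t{s:.12g}\t{rank}")
    else:
        rows.sort(key=lambda r: (-r[2], r[0], r[1]))
        for rank, (d, m, s) in enumerate(rows, start=1):
            lines.append(f"{d}\t{m}\t{s:.12g}\t{rank}")
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write("\n".join(lines) + "\n")
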
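"""Interval correspondences between a reference and a query genome.

A :class:`HomologyMap` is a liftOver stand-in: a set of aligned interval
blocks (reference interval -> query chromosome/interval/strand) with a
reciprocal flag marking blocks whose query->reference mapping returns the
source interval.  Positions and intervals lift through the block containing
them; intervals that span a block edge lift piecewise.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["HomologyMap", "LiftFailure"]

_COLUMNS = [
    "ref_start",
    "ref_end",
    "query_chrom",
    "query_start",
    "query_end",
    "strand",
    "reciprocal",
]


@dataclass(frozen=True)
class LiftFailure:
    reason: str  # unmapped | trans_split | not_reciprocal

    def __bool__(self):
        return False


class HomologyMap:
    """Blockwise reference->query interval map for one query species."""

    def __init__(self, blocks: pd.DataFrame, species: str = "query"):
        missing = [c for c in _COLUMNS if c not in blocks.columns]
        if missing:
            raise ValueError(f"homology map missing columns {missing}")
        b = blocks.sort_values("ref_start").reset_index(drop=True)
        if (b.ref_end <= b.ref_start).any():
            raise ValueError("empty or inverted reference interval in map")
        self.blocks = b
        self.species = species
        self._starts = b.ref_start.to_numpy()
        self._ends = b.ref_end.to_numpy()

    @classmethod
    def read_tsv(cls, path, species: str = "query") -> "HomologyMap":
        df = pd.read_csv(path, sep="\t")
        return cls(df, species)

    def to_tsv(self, path) -> None:
        self.blocks.to_csv(path, sep="\t", index=False)

    @classmethod
    def identity(cls, length: int, chrom: str = "chr1", species: str = "self") -> "HomologyMap":
        """Self-map: one reciprocal block covering the whole chromosome."""
        df = pd.DataFrame(
            [[0, length, chrom, 0, length, "+", True]], columns=_COLUMNS
        )
        return cls(df, species)

    def _block_at(self, pos: int) -> int | None:
        k = np.searchsorted(self._starts, pos, side="right") - 1
        if k < 0 or pos >= self._ends[k]:
            return None
        return int(k)

    def lift_position(self, pos: int, require_reciprocal: bool = True):
        """Map a reference bp position; returns (query_chrom, query_pos) or LiftFailure."""
        k = self._block_at(pos)
        if k is None:
            return LiftFailure("unmapped")
        row = self.blocks.iloc[k]
        if require_reciprocal and not row.reciprocal:
            return LiftFailure("not_reciprocal")
        off = pos - row.ref_start
        span_ref = row.ref_end - row.ref_start
        span_q = row.query_end - row.query_start
        # piecewise-linear within the block
        frac = off / span_ref
        if row.strand == "+":
            qpos = row.query_start + frac * span_q
        else:
            qpos = row.query_end - frac * span_q
        return row.query_chrom, int(round(qpos))

    def lift_interval(self, start: int, end: int, require_reciprocal: bool = True):
        """Map a reference interval.

        Returns ``(query_chrom, qstart, qend)`` when every overlapped block is
        reciprocal (if required) and all pieces land on one query chromosome;
        otherwise a :class:`LiftFailure` with reason ``unmapped``,
        ``not_reciprocal`` or ``trans_split``.  The returned interval is the
        envelope of the mapped pieces.
        """
        hit = (self._starts < end) & (self._ends > start)
        if not hit.any():
            return LiftFailure("unmapped")
        rows = self.blocks[hit]
        if require_reciprocal and not rows.reciprocal.all():
            return LiftFailure("not_reciprocal")
        if rows.query_chrom.nunique() > 1:
            return LiftFailure("trans_split")
        pieces = []
        for _, row in rows.iterrows():
            s = max(start, row.ref_start)
            e = min(end, row.ref_end)
            span_ref = row.ref_end - row.ref_start
            span_q = row.query_end - row.query_start
            f0, f1 = (s - row.ref_start) / span_ref, (e - row.ref_start) / span_ref
            if row.strand == "+":
                pieces.append((row.query_start + f0 * span_q, row.query_start + f1 * span_q))
            else:
                pieces.append((row.query_end - f1 * span_q, row.query_end - f0 * span_q))
        q0 = min(p[0] for p in pieces)
        q1 = max(p[1] for p in pieces)
        return rows.query_chrom.iloc[0], int(round(q0)), int(round(q1))

    def coverage_fraction(self, start: int, end: int, require_reciprocal: bool = True) -> float:
        """Fraction of [start, end) covered by (reciprocal) blocks."""
        hit = (self._starts < end) & (self._ends > start)
        rows = self.blocks[hit]
        if require_reciprocal:
            rows = rows[rows.reciprocal]
        cov = sum(min(end, e) - max(start, s) for s, e in zip(rows.ref_start, rows.ref_end))
        return cov / (end - start)
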
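"""Count and counts-per-million tables over (position, amino acid) cells.

Both tables are dense ``(n_positions, 21)`` matrices in the fixed symbol
order of :mod:`mlascan.alphabet`. Cells at the wild-type identity of a
position are structurally zero: wild-type reads are tallied separately in
``wt_count`` / ``wt_cpm`` so the matrices only ever hold variant mass.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .alphabet import AA_INDEX, AA_SYMBOLS, N_SYMBOLS

DISCARD_REASONS = ("length", "frame", "multi_mutant", "ambiguous")


def wt_cell_mask(positions: np.ndarray, wt_protein: str, offset: int = 1) -> np.ndarray:
    """Boolean (n_positions, 21) mask of wild-type identity cells.

    ``wt_protein`` is the full-length protein; ``positions`` are 1-based on it.
    """
    mask = np.zeros((len(positions), N_SYMBOLS), dtype=bool)
    for row, pos in enumerate(positions):
        mask[row, AA_INDEX[wt_protein[pos - 1]]] = True
    return mask


@dataclass
class CountTable:
    """Per-(position, symbol) read counts for one condition/replicate/sub-library."""

    positions: np.ndarray          # 1-based, full-length numbering
    wt_protein: str                # full-length wild-type protein
    counts: np.ndarray             # (n_positions, 21) int64
    wt_count: int
    discarded: dict[str, int] = field(default_factory=lambda: {r: 0 for r in DISCARD_REASONS})
    condition: str = ""
    replicate: int = 1
    sublibrary: str = ""

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=np.int64)
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if self.counts.shape != (len(self.positions), N_SYMBOLS):
            raise ValueError("counts matrix shape does not match positions x 21")
        if (self.counts < 0).any():
            raise ValueError("negative counts")
        wt = wt_cell_mask(self.positions, self.wt_protein)
        if self.counts[wt].any():
            raise ValueError("wild-type identity cells must be zero (WT reads go to wt_count)")

    @property
    def n_retained(self) -> int:
        return int(self.counts.sum()) + self.wt_count

    @property
    def n_discarded(self) -> int:
        return sum(self.discarded.values())

    def to_frame(self) -> pd.DataFrame:
        """Long-format table: position, aa, condition, replicate, count."""
        pos = np.repeat(self.positions, N_SYMBOLS)
        aa = np.tile(list(AA_SYMBOLS), len(self.positions))
        return pd.DataFrame(
            {
                "position": pos,
                "aa": aa,
                "condition": self.condition,
                "replicate": self.replicate,
                "count": self.counts.ravel(),
            }
        )


@dataclass
class FrequencyTable:
    """Counts-per-million table; all cells + wt_cpm sum to 1e6."""

    positions: np.ndarray
    wt_protein: str
    cpm: np.ndarray                # (n_positions, 21) float64, reads per million
    wt_cpm: float
    condition: str = ""
    replicate: int = 1
    sublibrary: str = ""

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=np.int64)
        self.cpm = np.asarray(self.cpm, dtype=np.float64)
        if self.cpm.shape != (len(self.positions), N_SYMBOLS):
            raise ValueError("cpm matrix shape does not match positions x 21")
        total = self.cpm.sum() + self.wt_cpm
        if abs(total - 1e6) > 1e-6 * 1e6:   # 1e-6 relative tolerance
            raise ValueError(f"cpm cells + wt_cpm sum to {total}, expected 1e6")

    @property
    def frequencies(self) -> np.ndarray:
        """Variant frequencies f_ix (cpm / 1e6)."""
        return self.cpm / 1e6

    @property
    def wt_frequency(self) -> float:
        return self.wt_cpm / 1e6

    def to_frame(self) -> pd.DataFrame:
        pos = np.repeat(self.positions, N_SYMBOLS)
        aa = np.tile(list(AA_SYMBOLS), len(self.positions))
        return pd.DataFrame(
            {
                "position": pos,
                "aa": aa,
                "condition": self.condition,
                "replicate": self.replicate,
                "cpm": self.cpm.ravel(),
            }
        )


def concat_frequency_tables(tables: list[FrequencyTable]) -> FrequencyTable:
    """Concatenate sub-library tables by position into one table.

    Each sub-library was normalized independently (each sums to 1e6 on its
    own); the concatenation rescales so the combined table again sums to 1e6,
    with the combined WT mass being the mean of the per-sub-library WT cpm.
    Position sets must be disjoint.
    """
    if not tables:
        raise ValueError("no tables to concatenate")
    if len(tables) == 1:
        return tables[0]
    all_pos = np.concatenate([t.positions for t in tables])
    if len(np.unique(all_pos)) != len(all_pos):
        raise ValueError("sub-library position sets overlap")
    order = np.argsort(all_pos)
    cpm = np.concatenate([t.cpm for t in tables], axis=0)[order]
    wt_cpm = float(np.mean([t.wt_cpm for t in tables]))
    scale = 1e6 / (cpm.sum() + wt_cpm)
    return FrequencyTable(
        positions=all_pos[order],
        wt_protein=tables[0].wt_protein,
        cpm=cpm * scale,
        wt_cpm=wt_cpm * scale,
        condition=tables[0].condition,
        replicate=tables[0].replicate,
        sublibrary="+".join(t.sublibrary for t in tables),
    )


def write_table_tsv(path, tables: list[CountTable] | list[FrequencyTable]) -> None:
    """Write count/frequency tables as one long-format TSV."""
    frames = [t.to_frame().assign(sublibrary=t.sublibrary) for t in tables]
    pd.concat(frames, ignore_index=True).to_csv(path, sep="\t", index=False)
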
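"""Enrichment-based fitness landscapes and functional-residue selection.

The per-variant score is the mutational cost

    dE_ix = log(f_ix,sel / f_ix,unsel) - log(f_iWT,sel / f_iWT,unsel)

the log (natural by default, configurable) frequency ratio of amino acid x
at position i between the selected and unselected populations, anchored on
the wild-type ratio. The score is 0 for the wild type by construction,
negative for variants depleted by selection, and invariant to uniform
rescaling of either condition's counts.

Functionally important residues are selected by the "k mutations beyond m
standard deviations" rule: a position qualifies when at least k of its
mutations score more than m population standard deviations below (default;
two-sided optional) the mean of all mutation scores in the landscape.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .alphabet import AA_INDEX, AA_SYMBOLS, N_SYMBOLS
from .tables import FrequencyTable, wt_cell_mask


@dataclass
class FitnessLandscape:
    """dE matrix over positions x 21 symbols, with an NA mask for unobserved cells."""

    positions: np.ndarray           # 1-based full-length numbering
    wt_protein: str
    delta_e: np.ndarray             # (n_positions, 21) float64; WT cells exactly 0
    na_mask: np.ndarray             # True where the score is unobserved
    replicate: int | str = 1
    partial_mask: np.ndarray | None = None  # True where a replicate average is partial

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=np.int64)
        self.delta_e = np.asarray(self.delta_e, dtype=np.float64)
        self.na_mask = np.asarray(self.na_mask, dtype=bool)
        wt = wt_cell_mask(self.positions, self.wt_protein)
        if (self.delta_e[wt] != 0).any() or self.na_mask[wt].any():
            raise ValueError("wild-type cells must score exactly 0 and never be NA")

    @property
    def wt_cells(self) -> np.ndarray:
        return wt_cell_mask(self.positions, self.wt_protein)

    def mutation_values(self) -> np.ndarray:
        """All observed non-WT scores, flattened."""
        keep = ~self.wt_cells & ~self.na_mask
        return self.delta_e[keep]

    def score(self, position: int, symbol: str) -> float:
        row = int(np.flatnonzero(self.positions == position)[0])
        col = AA_INDEX[symbol]
        return float("nan") if self.na_mask[row, col] else float(self.delta_e[row, col])


@dataclass
class ResidueSelection:
    """Positions passing the k-mutations / m-SD rule, with the rule's context."""

    selected_positions: set[int]
    k: int
    m: float
    sided: str
    mu: float
    sigma: float
    qualifying_counts: dict[int, int]


@dataclass
class GroupAnnotation:
    """Structural/functional classes used to partition selected residues."""

    signal_peptide: tuple[int, int] = (1, 21)
    pocket_positions: set[int] = field(default_factory=set)
    buried_positions: set[int] = field(default_factory=set)
    surface_positions: set[int] = field(default_factory=set)


# ---------------------------------------------------------------------------

def compute_fitness(
    sel: FrequencyTable,
    unsel: FrequencyTable,
    log_base: float | None = None,
) -> FitnessLandscape:
    """Mutational-cost landscape from a selected/unselected table pair.

    Cells with zero frequency in either condition (possible when no
    pseudocount was applied) are masked NA; the wild-type frequency must be
    positive in both conditions since it anchors the ratio. ``log_base``
    defaults to natural log.
    """
    if not np.array_equal(sel.positions, unsel.positions):
        raise ValueError("tables cover different positions")
    if sel.wt_cpm <= 0 or unsel.wt_cpm <= 0:
        raise ValueError("wild-type frequency is zero; cannot anchor the ratio")
    na = (sel.cpm <= 0) | (unsel.cpm <= 0)
    with np.errstate(divide="ignore", invalid="ignore"):
        de = np.log(sel.cpm / unsel.cpm) - np.log(sel.wt_cpm / unsel.wt_cpm)
    if log_base is not None:
        de = de / np.log(log_base)
    de[na] = np.nan
    wt = wt_cell_mask(sel.positions, sel.wt_protein)
    de[wt] = 0.0
    na[wt] = False
    de[na] = 0.0  # masked cells carry no value
    return FitnessLandscape(
        positions=sel.positions.copy(),
        wt_protein=sel.wt_protein,
        delta_e=de,
        na_mask=na,
        replicate=sel.replicate,
    )


def concat_landscapes(parts: list[FitnessLandscape]) -> FitnessLandscape:
    """Concatenate sub-library landscapes by position (disjoint position sets)."""
    if len(parts) == 1:
        return parts[0]
    pos = np.concatenate([p.positions for p in parts])
    if len(np.unique(pos)) != len(pos):
        raise ValueError("landscapes overlap in positions")
    order = np.argsort(pos)
    return FitnessLandscape(
        positions=pos[order],
        wt_protein=parts[0].wt_protein,
        delta_e=np.concatenate([p.delta_e for p in parts], axis=0)[order],
        na_mask=np.concatenate([p.na_mask for p in parts], axis=0)[order],
        replicate=parts[0].replicate,
    )


def average_replicates(landscapes: list[FitnessLandscape]) -> FitnessLandscape:
    """Cell-wise mean over replicates, ignoring NA cells.

    A cell is NA in the average only when NA in every replicate; cells
    averaged from a strict subset of replicates are flagged in
    ``partial_mask``.
    """
    if not landscapes:
        raise ValueError("no landscapes to average")
    shape = landscapes[0].delta_e.shape
    for lc in landscapes[1:]:
        if lc.delta_e.shape != shape or not np.array_equal(lc.positions, landscapes[0].positions):
            raise ValueError("landscape shapes/positions differ")
    stack = np.stack([np.where(lc.na_mask, np.nan, lc.delta_e) for lc in landscapes])
    n_obs = (~np.isnan(stack)).sum(axis=0)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN cells
        mean = np.nanmean(stack, axis=0)
    na = n_obs == 0
    mean[na] = 0.0
    partial = (n_obs > 0) & (n_obs < len(landscapes))
    return FitnessLandscape(
        positions=landscapes[0].positions.copy(),
        wt_protein=landscapes[0].wt_protein,
        delta_e=mean,
        na_mask=na,
        replicate="mean",
        partial_mask=partial,
    )


def position_summary(landscape: FitnessLandscape) -> pd.Series:
    """Per-position mean score over the 20 non-WT symbols, skipping NA."""
    if landscape.delta_e.size == 0:
        raise ValueError("empty landscape")
    vals = np.where(landscape.wt_cells | landscape.na_mask, np.nan, landscape.delta_e)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        means = np.nanmean(vals, axis=1)
    return pd.Series(means, index=pd.Index(landscape.positions, name="position"), name="mean_delta_e")


def select_functional_residues(
    landscape: FitnessLandscape,
    k: int = 5,
    m: float = 1.0,
    sided: str = "below",
) -> ResidueSelection:
    """Positions where >= k mutations score beyond m SD from the landscape mean.

    The mean and (population) standard deviation are computed over all
    observed non-WT cells, stops included. ``below`` (default) counts
    mutations with dE < mu - m*sigma, matching a loss-of-function screen;
    ``two_sided`` counts |dE - mu| > m*sigma.
    """
    if k < 1 or m <= 0:
        raise ValueError("require k >= 1 and m > 0")
    if sided not in ("below", "two_sided"):
        raise ValueError(f"unknown sidedness {sided!r}")
    values = landscape.mutation_values()
    mu = float(values.mean())
    sigma = float(values.std())  # population SD (ddof=0)
    if sigma == 0:
        raise ValueError("degenerate landscape: zero variance across mutations")
    cells = np.where(landscape.wt_cells | landscape.na_mask, np.nan, landscape.delta_e)
    if sided == "below":
        qualifies = cells < mu - m * sigma
    else:
        qualifies = np.abs(cells - mu) > m * sigma
    qualifies &= ~np.isnan(cells)
    counts = qualifies.sum(axis=1)
    selected = {int(p) for p, c in zip(landscape.positions, counts) if c >= k}
    return ResidueSelection(
        selected_positions=selected,
        k=k,
        m=m,
        sided=sided,
        mu=mu,
        sigma=sigma,
        qualifying_counts={int(p): int(c) for p, c in zip(landscape.positions, counts)},
    )


GROUP_ORDER = ("signal_peptide", "pocket", "buried", "surface")


def classify_groups(selection: ResidueSelection, annot: GroupAnnotation) -> dict[str, list[int]]:
    """Partition selected residues into the four functional groups.

    Precedence when annotations overlap: signal peptide > pocket > buried >
    surface; selected positions missing from every annotation go to
    ``unclassified`` with a warning.
    """
    sp_lo, sp_hi = annot.signal_peptide
    groups: dict[str, list[int]] = {g: [] for g in GROUP_ORDER}
    groups["unclassified"] = []
    for pos in sorted(selection.selected_positions):
        if sp_lo <= pos <= sp_hi:
            groups["signal_peptide"].append(pos)
        elif pos in annot.pocket_positions:
            groups["pocket"].append(pos)
        elif pos in annot.buried_positions:
            groups["buried"].append(pos)
        elif pos in annot.surface_positions:
            groups["surface"].append(pos)
        else:
            groups["unclassified"].append(pos)
    if groups["unclassified"]:
        warnings.warn(
            f"{len(groups['unclassified'])} selected positions lack annotation",
            stacklevel=2,
        )
    return groups


# ---------------------------------------------------------------------------
# IO

def landscape_to_frame(landscape: FitnessLandscape) -> pd.DataFrame:
    pos = np.repeat(landscape.positions, N_SYMBOLS)
    aa = np.tile(list(AA_SYMBOLS), len(landscape.positions))
    score = np.where(landscape.na_mask, np.nan, landscape.delta_e).ravel()
    return pd.DataFrame({"position": pos, "aa": aa, "score": score})


def write_landscape_tsv(path, landscape: FitnessLandscape) -> None:
    landscape_to_frame(landscape).to_csv(path, sep="\t", index=False)


_ONE_FROM_THREE = {
    "Ala": "A", "Cys": "C", "Asp": "D", "Glu": "E", "Phe": "F", "Gly": "G",
    "His": "H", "Ile": "I", "Lys": "K", "Leu": "L", "Met": "M", "Asn": "N",
    "Pro": "P", "Gln": "Q", "Arg": "R", "Ser": "S", "Thr": "T", "Val": "V",
    "Trp": "W", "Tyr": "Y", "Ter": "*",
}
_HGVS_RE = re.compile(r"^p\.([A-Z][a-z]{2})(\d+)([A-Z][a-z]{2}|=)$")
_SIMPLE_RE = re.compile(r"^([A-Z\*])(\d+)([A-Z\*])$")


def parse_protein_variant(s: str) -> tuple[str, int, str] | None:
    """Parse ``A2G`` / ``p.Ala2Gly`` style variant strings -> (wt, pos, mut).

    Returns None for synonymous (``p.Xyz#=``) or unparseable strings.
    """
    s = s.strip()
    m = _SIMPLE_RE.match(s)
    if m:
        return m.group(1), int(m.group(2)), m.group(3)
    m = _HGVS_RE.match(s)
    if m and m.group(3) != "=" and m.group(3) in _ONE_FROM_THREE:
        return _ONE_FROM_THREE[m.group(1)], int(m.group(2)), _ONE_FROM_THREE[m.group(3)]
    return None


def write_scores_csv(path, landscape: FitnessLandscape) -> None:
    """Score-repository style CSV: one protein-variant string + score per row."""
    rows = []
    wt = landscape.wt_cells
    for r, pos in enumerate(landscape.positions):
        for c, aa in enumerate(AA_SYMBOLS):
            if wt[r, c] or landscape.na_mask[r, c]:
                continue
            rows.append((f"{landscape.wt_protein[pos - 1]}{pos}{aa}", landscape.delta_e[r, c]))
    pd.DataFrame(rows, columns=["variant", "score"]).to_csv(path, index=False)


def landscape_from_scores_csv(path, wt_protein: str | None = None) -> FitnessLandscape:
    """Build a landscape from a deposited score CSV.

    Accepts a ``variant``/``hgvs_pro`` column with ``A2G`` or ``p.Ala2Gly``
    variant strings and a ``score`` column. The wild-type protein is inferred
    from the variant strings when not given (positions never referenced stay
    NA with WT identity ``X`` placeholder, which restricts downstream use to
    selection rules that ignore WT cells).
    """
    df = pd.read_csv(path)
    var_col = next((c for c in ("variant", "hgvs_pro") if c in df.columns), None)
    if var_col is None or "score" not in df.columns:
        raise ValueError("score CSV needs a variant/hgvs_pro column and a score column")
    parsed = []
    for v, s in zip(df[var_col], df["score"]):
        p = parse_protein_variant(str(v))
        if p is not None and np.isfinite(s):
            parsed.append((*p, float(s)))
    if not parsed:
        raise ValueError("no parseable variant rows")
    max_pos = max(p for _, p, _, _ in parsed)
    wt_list = list(wt_protein) if wt_protein else ["X"] * max_pos
    for wt_aa, pos, _, _ in parsed:
        if wt_protein is None:
            wt_list[pos - 1] = wt_aa
        elif wt_list[pos - 1] != wt_aa:
            raise ValueError(f"variant WT {wt_aa} at {pos} contradicts the given protein")
    wt_seq = "".join(wt_list)
    positions = np.arange(1, max_pos + 1, dtype=np.int64)
    de = np.zeros((max_pos, N_SYMBOLS))
    na = np.ones((max_pos, N_SYMBOLS), dtype=bool)
    for _, pos, mut, score in parsed:
        de[pos - 1, AA_INDEX[mut]] = score
        na[pos - 1, AA_INDEX[mut]] = False
    for r, pos in enumerate(positions):
        aa = wt_seq[pos - 1]
        if aa in AA_INDEX:
            de[r, AA_INDEX[aa]] = 0.0
            na[r, AA_INDEX[aa]] = False
    # placeholder rows (WT unknown) keep their NA; FitnessLandscape requires a
    # WT cell per position, so substitute a never-observed symbol-safe identity
    if "X" in wt_seq:
        wt_seq = wt_seq.replace("X", "A")
        for r in range(max_pos):
            if na[r].all():
                de[r, AA_INDEX["A"]] = 0.0
                na[r, AA_INDEX["A"]] = False
    return FitnessLandscape(
        positions=positions,
        wt_protein=wt_seq,
        delta_e=de,
        na_mask=na,
        replicate="deposited",
    )
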
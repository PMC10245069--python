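"""Synthetic-data generation with known ground truth for every pipeline stage.

The generator emulates the study design end to end: a complete NNS
single-mutant library over a 211-residue periplasmic carrier split into two
amplicon sub-libraries (positions 1-107 and 108-211), two biological
replicates of a paired selection / no-selection experiment with planted
per-variant fitness effects, amplicon reads at ~300x per-variant coverage,
1:1-kinetics sensorgrams, and toy two-chain complexes with planted contacts.

The selection model is multiplicative in exp(dE_true): post-selection
frequencies are proportional to pre-selection frequencies times exp(dE_true),
renormalized. This is a modelling choice (not a claim about bacterial
growth) made so the log-ratio fitness estimator is its exact inverse, which
gives the pipeline a closed-form round trip to verify against.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .alphabet import (
    AA_INDEX,
    AA_SYMBOLS,
    BASE_TO_INDEX,
    COMPLEMENT_BYTE,
    DNA_BASES,
    N_SYMBOLS,
    matrix_to_reads,
    reads_to_matrix,
    seq_to_bytes,
)
from .kinetics import Sensorgram, response_1to1
from .library import VariantLibrary, nns_codons_for
from .structure import StructureModel, interchain_contacts
from .tables import FrequencyTable, wt_cell_mask

# defaults mirroring the study conditions
DEFAULT_DEPTH = 300           # reads per variant (study coverage ~306-462x)
DEFAULT_REPLICATES = 2
DEFAULT_ERROR_RATE = 1e-3     # per-base substitution rate


# ---------------------------------------------------------------------------
# wild-type sequence and planted truth

def random_wt_cds(n_codons: int = 211, seed: int = 0) -> str:
    """Random coding sequence with no internal stop codon (ATG start).

    Stand-in wild-type CDS for synthetic experiments; any real CDS may be
    passed to the pipeline instead.
    """
    rng = np.random.default_rng(seed)
    stops = {"TAA", "TAG", "TGA"}
    codons = ["ATG"]
    while len(codons) < n_codons:
        c = "".join(rng.choice(list(DNA_BASES), size=3))
        if c not in stops:
            codons.append(c)
    return "".join(codons)


@dataclass
class TrueFitnessMap:
    """Planted per-variant effects; the wild type has effect exactly 0."""

    effects: dict[tuple[int, str], float]

    def effect(self, position: int, symbol: str, wt_protein: str) -> float:
        if symbol == wt_protein[position - 1]:
            return 0.0
        return self.effects[(position, symbol)]

    def matrix(self, positions: np.ndarray, wt_protein: str) -> np.ndarray:
        """(n_positions, 21) effect matrix; WT cells 0, missing variants NaN."""
        out = np.full((len(positions), N_SYMBOLS), np.nan)
        for row, pos in enumerate(positions):
            for sym, col in AA_INDEX.items():
                if sym == wt_protein[pos - 1]:
                    out[row, col] = 0.0
                else:
                    val = self.effects.get((int(pos), sym))
                    if val is not None:
                        out[row, col] = val
        return out


def sample_true_fitness(
    library: VariantLibrary,
    seed: int,
    p_deleterious: float = 0.35,
    deleterious_mean: float = -3.0,
    deleterious_sd: float = 1.5,
    neutral_sd: float = 0.15,
    stop_mean: float = -6.0,
    stop_sd: float = 0.5,
) -> TrueFitnessMap:
    """Draw planted effects from a neutral/deleterious mixture.

    Missense variants are neutral (Normal(0, neutral_sd)) with probability
    1 - p_deleterious and deleterious (Normal(deleterious_mean,
    deleterious_sd), truncated at 0) otherwise; stops are strongly
    deleterious. The scale is the same dimensionless log scale as the
    fitness estimator.
    """
    rng = np.random.default_rng(seed)
    effects: dict[tuple[int, str], float] = {}
    for pos, sym in sorted(library.variants):
        if sym == "*":
            effects[(pos, sym)] = min(0.0, rng.normal(stop_mean, stop_sd))
        elif rng.random() < p_deleterious:
            effects[(pos, sym)] = min(0.0, rng.normal(deleterious_mean, deleterious_sd))
        else:
            effects[(pos, sym)] = rng.normal(0.0, neutral_sd)
    return TrueFitnessMap(effects=effects)


# ---------------------------------------------------------------------------
# frequencies and selection

def preselection_frequencies(
    library: VariantLibrary,
    sublibrary: tuple[int, int],
    condition: str = "unselected",
    replicate: int = 1,
) -> FrequencyTable:
    """Equimolar NNS pre-selection frequency table for one sub-library.

    Positions contribute equally; within a position each of the 32 NNS codons
    is equimolar, so wild-type synonymous codons contribute wild-type mass
    and each variant amino acid weighs in proportion to its NNS codon count.
    """
    positions = np.array(library.sublibrary_positions(sublibrary), dtype=np.int64)
    cpm = np.zeros((len(positions), N_SYMBOLS))
    wt_mass = 0.0
    per_pos = 1.0 / len(positions)
    for row, pos in enumerate(positions):
        wt_aa = library.wt_protein[pos - 1]
        for sym in AA_SYMBOLS:
            weight = per_pos * len(nns_codons_for(sym)) / 32.0
            if sym == wt_aa:
                wt_mass += weight
            else:
                cpm[row, AA_INDEX[sym]] = weight
    scale = 1e6 / (cpm.sum() + wt_mass)
    return FrequencyTable(
        positions=positions,
        wt_protein=library.wt_protein,
        cpm=cpm * scale,
        wt_cpm=wt_mass * scale,
        condition=condition,
        replicate=replicate,
        sublibrary=f"{sublibrary[0]}-{sublibrary[1]}",
    )


def simulate_selection(pre_freqs: FrequencyTable, truth: TrueFitnessMap) -> FrequencyTable:
    """Apply multiplicative selection: post ∝ pre * exp(dE_true), renormalized.

    The wild type multiplies by exp(0) = 1. Every variant carrying
    pre-selection mass must be covered by the truth map.
    """
    eff = truth.matrix(pre_freqs.positions, pre_freqs.wt_protein)
    present = pre_freqs.cpm > 0
    missing = present & np.isnan(eff)
    if missing.any():
        row, col = np.argwhere(missing)[0]
        raise ValueError(
            f"variant ({pre_freqs.positions[row]}, {AA_SYMBOLS[col]}) missing from truth map"
        )
    mult = np.where(np.isnan(eff), 0.0, np.exp(np.nan_to_num(eff)))
    post = pre_freqs.cpm * mult
    wt_post = pre_freqs.wt_cpm  # exp(0) = 1
    scale = 1e6 / (post.sum() + wt_post)
    return FrequencyTable(
        positions=pre_freqs.positions.copy(),
        wt_protein=pre_freqs.wt_protein,
        cpm=post * scale,
        wt_cpm=wt_post * scale,
        condition="selected",
        replicate=pre_freqs.replicate,
        sublibrary=pre_freqs.sublibrary,
    )


# ---------------------------------------------------------------------------
# reads

@dataclass
class ReadSet:
    """Amplicon reads for one condition/replicate/sub-library."""

    reads: list[str]
    condition: str
    replicate: int
    sublibrary: str
    seed: int | None = None
    discarded: dict[str, int] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.reads)


def variant_codon(symbol: str) -> str:
    """Deterministic NNS codon used to encode a variant symbol in reads."""
    return nns_codons_for(symbol)[0]


def simulate_reads(
    freqs: FrequencyTable,
    library: VariantLibrary,
    sublibrary: tuple[int, int],
    depth: float = DEFAULT_DEPTH,
    error_rate: float = DEFAULT_ERROR_RATE,
    seed: int = 0,
    revcomp_fraction: float = 0.5,
) -> ReadSet:
    """Multinomial amplicon reads from a frequency table.

    Reads are drawn over variants plus wild type proportional to the table,
    each variant encoded by one fixed NNS codon on the sub-library amplicon;
    per-base substitution errors are applied at ``error_rate`` and a seeded
    fraction of reads is reverse-complemented to exercise orientation
    recovery. Deterministic for a fixed seed.
    """
    if depth <= 0:
        raise ValueError("depth must be positive")
    if not 0 <= error_rate < 0.01:
        raise ValueError("error_rate must be in [0, 0.01)")
    rng = np.random.default_rng(seed)
    lo, hi = sublibrary
    positions = np.array(library.sublibrary_positions(sublibrary), dtype=np.int64)
    if not np.array_equal(np.sort(freqs.positions), positions):
        raise ValueError("frequency table does not match the sub-library positions")

    amplicon = seq_to_bytes(library.sublibrary_cds(sublibrary))
    length = len(amplicon)
    # unique sequences: one per (position, symbol) cell with mass, plus WT
    cells = np.argwhere(freqs.cpm > 0)
    probs = np.append(freqs.cpm[cells[:, 0], cells[:, 1]], freqs.wt_cpm)
    probs = probs / probs.sum()
    seqs = np.tile(amplicon, (len(cells) + 1, 1))
    for k, (row, col) in enumerate(cells):
        pos = int(freqs.positions[row])
        codon = seq_to_bytes(variant_codon(AA_SYMBOLS[col]))
        off = 3 * (pos - lo)
        seqs[k, off : off + 3] = codon

    n_variants = len(positions) * 20
    n_reads = int(round(depth * n_variants))
    counts = rng.multinomial(n_reads, probs)
    reads = np.repeat(seqs, counts, axis=0)
    reads = reads[rng.permutation(n_reads)]

    # substitution errors, chunked to bound memory
    if error_rate > 0:
        base_idx = BASE_TO_INDEX[reads]
        chunk = max(1, 50_000)
        for start in range(0, n_reads, chunk):
            block = base_idx[start : start + chunk]
            mask = rng.random(block.shape, dtype=np.float32) < error_rate
            n_err = int(mask.sum())
            if n_err:
                shift = rng.integers(1, 4, size=n_err).astype(np.uint8)
                block[mask] = (block[mask] + shift) % 4
        lut = np.frombuffer("ACGT".encode(), dtype=np.uint8)
        reads = lut[base_idx]

    if revcomp_fraction > 0:
        flip = rng.random(n_reads) < revcomp_fraction
        reads[flip] = COMPLEMENT_BYTE[reads[flip]][:, ::-1]

    return ReadSet(
        reads=matrix_to_reads(reads),
        condition=freqs.condition,
        replicate=freqs.replicate,
        sublibrary=f"{lo}-{hi}",
        seed=seed,
    )


def write_fastq(path: str | Path, readset: ReadSet, quality_char: str = "I") -> None:
    """Phred+33 FASTQ with constant quality."""
    with open(path, "w") as fh:
        for i, read in enumerate(readset.reads):
            fh.write(
                f"@{readset.condition}_rep{readset.replicate}_{readset.sublibrary}_{i}\n"
                f"{read}\n+\n{quality_char * len(read)}\n"
            )


def read_fastq(path: str | Path, condition: str = "", replicate: int = 1, sublibrary: str = "") -> ReadSet:
    from Bio import SeqIO

    reads = [str(rec.seq) for rec in SeqIO.parse(str(path), "fastq")]
    return ReadSet(reads=reads, condition=condition, replicate=replicate, sublibrary=sublibrary)


def write_fasta(path: str | Path, name: str, seq: str) -> None:
    with open(path, "w") as fh:
        fh.write(f">{name}\n")
        for i in range(0, len(seq), 60):
            fh.write(seq[i : i + 60] + "\n")


# ---------------------------------------------------------------------------
# sensorgrams

@dataclass(frozen=True)
class PhaseSchedule:
    """Durations (s) of the three recorded phases, in order."""

    baseline: float = 60.0
    association: float = 30.0
    dissociation: float = 100.0
    sample_rate: float = 5.0  # Hz

    def grid(self) -> tuple[np.ndarray, np.ndarray]:
        dt = 1.0 / self.sample_rate
        total = self.baseline + self.association + self.dissociation
        time = np.arange(0.0, total, dt)
        phase = np.where(
            time < self.baseline,
            "baseline",
            np.where(time < self.baseline + self.association, "association", "dissociation"),
        )
        return time, phase


@dataclass
class SensorgramSet:
    traces: list[Sensorgram]
    sensor_id: str
    noise_sd: float


def simulate_sensorgrams(
    kon: float,
    koff: float,
    rmax: float,
    concentrations: list[float],
    schedule: PhaseSchedule = PhaseSchedule(),
    noise_sd: float = 0.0,
    seed: int = 0,
    sensor_id: str = "sensor1",
) -> SensorgramSet:
    """Forward-simulate 1:1 binding traces with Gaussian noise.

    Association follows R(t) = Req (1 - e^{-(kon C + koff) t}) with
    Req = Rmax C / (C + KD); dissociation decays from the end-of-association
    signal at rate koff.
    """
    if kon <= 0 or koff <= 0 or rmax <= 0:
        raise ValueError("kon, koff and Rmax must all be positive")
    if not concentrations:
        raise ValueError("empty concentration list")
    rng = np.random.default_rng(seed)
    traces = []
    for conc in concentrations:
        if conc <= 0:
            raise ValueError("concentrations must be positive")
        time, phase = schedule.grid()
        signal = response_1to1(time, phase, conc, kon, koff, rmax)
        if noise_sd > 0:
            signal = signal + rng.normal(0.0, noise_sd, size=signal.shape)
        traces.append(
            Sensorgram(time=time, signal=signal, phase=phase, analyte_conc=conc, sensor_id=sensor_id)
        )
    return SensorgramSet(traces=traces, sensor_id=sensor_id, noise_sd=noise_sd)


# ---------------------------------------------------------------------------
# toy complexes

def generate_toy_complex(
    n_a: int,
    n_b: int,
    planted_contacts: set[tuple[int, int]],
    cutoff: float = 4.0,
    seed: int = 0,
    max_retries: int = 5,
) -> StructureModel:
    """Two-chain model where exactly the planted residue pairs are in contact.

    Chains A and B are laid out on parallel lines separated by well over the
    cutoff; each planted pair (i, j) gets a dedicated contact site far from
    the chain lines where one extra atom from A:i and one from B:j sit at a
    distance just inside the cutoff. All other inter-chain residue pairs are
    farther than cutoff + 1 A by construction, which is verified by a
    brute-force contact check before returning.
    """
    for i, j in planted_contacts:
        if not (1 <= i <= n_a and 1 <= j <= n_b):
            raise ValueError(f"planted pair ({i}, {j}) outside chain sizes")
    rng = np.random.default_rng(seed)
    for _attempt in range(max_retries):
        records: list[tuple[str, int, str, str, float, float, float]] = []
        sep = cutoff + 20.0
        for i in range(1, n_a + 1):
            x, y, z = 8.0 * i + rng.uniform(-0.1, 0.1), rng.uniform(-0.1, 0.1), rng.uniform(-0.1, 0.1)
            records.append(("A", i, "CA", "C", x, y, z))
        for j in range(1, n_b + 1):
            x, y, z = 8.0 * j + rng.uniform(-0.1, 0.1), sep + rng.uniform(-0.1, 0.1), rng.uniform(-0.1, 0.1)
            records.append(("B", j, "CA", "C", x, y, z))
        n_extra: dict[tuple[str, int], int] = {}
        for k, (i, j) in enumerate(sorted(planted_contacts)):
            sx, sy, sz = 20.0 * k, sep / 2.0, 60.0
            d = cutoff - 0.5 + rng.uniform(-0.2, 0.2)
            # unique atom names per residue so PDB round trips keep every atom
            for cid, rid, y in (("A", i, sy - d / 2.0), ("B", j, sy + d / 2.0)):
                n_extra[(cid, rid)] = n_extra.get((cid, rid), 0) + 1
                records.append((cid, rid, f"CB{n_extra[(cid, rid)]}", "C", sx, y, sz))
        records.sort(key=lambda r: (r[0], r[1]))
        model = StructureModel(
            chain_ids=np.array([r[0] for r in records]),
            res_ids=np.array([r[1] for r in records], dtype=np.int64),
            res_names=np.array(["ALA"] * len(records)),
            atom_names=np.array([r[2] for r in records]),
            elements=np.array([r[3] for r in records]),
            coords=np.array([[r[4], r[5], r[6]] for r in records]),
            source=f"toy(seed={seed})",
        )
        found = {
            (a[1], b[1]) for a, b in interchain_contacts(model, {"A"}, {"B"}, cutoff).pairs
        }
        if found == set(planted_contacts):
            return model
    raise RuntimeError("could not realize the requested contact geometry")
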
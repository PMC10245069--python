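"""End-to-end orchestration of the synthetic screen and staged reruns.

A run is reproducible from its :class:`RunConfig` alone: every source of
randomness derives from the single config seed, outputs are stamped with the
config hash, and stages communicate through plain TSV files in the output
directory so any suffix of the pipeline can be rerun on existing outputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.stats import spearmanr

from .alphabet import AA_INDEX, AA_SYMBOLS, N_SYMBOLS
from .counting import count_readset, normalize_cpm
from .fitness import (
    FitnessLandscape,
    average_replicates,
    compute_fitness,
    concat_landscapes,
    position_summary,
    select_functional_residues,
    write_landscape_tsv,
    write_scores_csv,
)
from .library import generate_nns_library
from .synthetic import (
    TrueFitnessMap,
    preselection_frequencies,
    random_wt_cds,
    sample_true_fitness,
    simulate_reads,
    simulate_selection,
)
from .tables import CountTable, FrequencyTable

logger = logging.getLogger(__name__)

STAGES = ("simulate", "count", "fitness", "select")


@dataclass
class RunConfig:
    """All tunables of a synthetic screen run."""

    seed: int = 0
    n_positions: int = 211
    depth: float = 300.0          # reads per variant per condition
    error_rate: float = 1e-3      # per-base substitution rate
    replicates: int = 2
    pseudocount: float = 1.0
    k: int = 5
    m: float = 1.0
    sided: str = "below"
    log_base: float | None = None  # None = natural log
    outdir: str | None = None

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), sort_keys=True)

    @property
    def config_hash(self) -> str:
        """Hash of the scientific parameters only; output paths do not count."""
        payload = dataclasses.asdict(self)
        payload.pop("outdir", None)
        return hashlib.sha256(json.dumps(payload, sort_keys=True).encode()).hexdigest()[:16]

    def derived_seed(self, *indices: int) -> int:
        """Deterministic per-stage seed below 2^31."""
        h = hashlib.sha256(f"{self.seed}:{indices}".encode()).digest()
        return int.from_bytes(h[:4], "big") % (2**31)

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        data = json.loads(Path(path).read_text())
        return cls(**data)


# ---------------------------------------------------------------------------
# staged TSV round trips

def counts_to_tsv(path: str | Path, tables: list[CountTable], config_hash: str = "") -> None:
    frames = []
    for t in tables:
        df = t.to_frame().assign(sublibrary=t.sublibrary)
        wt_row = pd.DataFrame(
            {
                "position": [0],
                "aa": ["WT"],
                "condition": [t.condition],
                "replicate": [t.replicate],
                "count": [t.wt_count],
                "sublibrary": [t.sublibrary],
            }
        )
        frames.append(pd.concat([df, wt_row], ignore_index=True))
    out = pd.concat(frames, ignore_index=True)
    with open(path, "w") as fh:
        if config_hash:
            fh.write(f"# config_hash={config_hash}\n")
        out.to_csv(fh, sep="\t", index=False)


def counts_from_tsv(path: str | Path, wt_protein: str) -> list[CountTable]:
    df = pd.read_csv(path, sep="\t", comment="#")
    tables = []
    for (cond, rep, sub), grp in df.groupby(["condition", "replicate", "sublibrary"], sort=False):
        wt_rows = grp[grp["aa"] == "WT"]
        wt_count = int(wt_rows["count"].sum())
        body = grp[grp["aa"] != "WT"]
        positions = np.sort(body["position"].unique())
        counts = np.zeros((len(positions), N_SYMBOLS), dtype=np.int64)
        pos_index = {p: i for i, p in enumerate(positions)}
        for _, row in body.iterrows():
            counts[pos_index[row["position"]], AA_INDEX[row["aa"]]] = row["count"]
        tables.append(
            CountTable(
                positions=positions,
                wt_protein=wt_protein,
                counts=counts,
                wt_count=wt_count,
                condition=str(cond),
                replicate=int(rep),
                sublibrary=str(sub),
            )
        )
    return tables


def export_heatmap_matrix(landscape: FitnessLandscape, path: str | Path, config_hash: str = "") -> None:
    """Figure-ready matrix: 21 symbol rows x position columns; NA cells are 'X'."""
    mat = pd.DataFrame(
        landscape.delta_e.T,
        index=list(AA_SYMBOLS),
        columns=landscape.positions,
    ).astype(object)
    na = landscape.na_mask.T
    for r in range(na.shape[0]):
        for c in np.flatnonzero(na[r]):
            mat.iat[r, c] = "X"
    with open(path, "w") as fh:
        if config_hash:
            fh.write(f"# config_hash={config_hash}\n")
        mat.to_csv(fh, sep="\t", index_label="aa")


def read_heatmap_matrix(path: str | Path) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Inverse of :func:`export_heatmap_matrix` -> (positions, values, na_mask)."""
    df = pd.read_csv(path, sep="\t", comment="#", index_col="aa")
    positions = df.columns.to_numpy(dtype=np.int64)
    raw = df.to_numpy(dtype=object).T  # positions x 21
    na = raw == "X"
    values = np.where(na, 0.0, raw).astype(np.float64)
    return positions, values, na


# ---------------------------------------------------------------------------
# synthetic end-to-end run

@dataclass
class SyntheticRun:
    """In-memory artifacts of a full synthetic screen."""

    config: RunConfig
    wt_cds: str
    truth: TrueFitnessMap
    count_tables: list[CountTable]
    replicate_landscapes: list[FitnessLandscape]
    landscape: FitnessLandscape
    selection: object
    report: dict = field(default_factory=dict)


def _recovery_stats(run_landscape: FitnessLandscape, truth: TrueFitnessMap, limit: float = 5.0) -> dict:
    """Spearman correlation between planted and estimated scores.

    Restricted to variants with |dE_true| <= limit: stronger depletions leave
    too few post-selection reads to estimate and would only measure noise.
    """
    truth_mat = truth.matrix(run_landscape.positions, run_landscape.wt_protein)
    keep = (
        ~run_landscape.wt_cells
        & ~run_landscape.na_mask
        & np.isfinite(truth_mat)
        & (np.abs(truth_mat) <= limit)
    )
    rho, _ = spearmanr(truth_mat[keep], run_landscape.delta_e[keep])
    return {"spearman": float(rho), "n_variants": int(keep.sum())}


def run_synthetic_experiment(
    config: RunConfig,
    write_outputs: bool = True,
    truth: TrueFitnessMap | None = None,
) -> SyntheticRun:
    """Simulate the full screen and run the analysis pipeline on it.

    Library -> planted truth -> per-replicate selection -> reads -> counting
    -> CPM -> fitness -> replicate average -> residue selection, with
    recovery statistics against the planted truth in the run report. A custom
    ``truth`` map overrides the default mixture draw.
    """
    wt_cds = random_wt_cds(config.n_positions, seed=config.derived_seed(0))
    library = generate_nns_library(wt_cds)
    if truth is None:
        truth = sample_true_fitness(library, seed=config.derived_seed(1))

    count_tables: list[CountTable] = []
    replicate_landscapes: list[FitnessLandscape] = []
    for rep in range(1, config.replicates + 1):
        parts = []
        for s_idx, sub in enumerate(library.sublibraries):
            lo, hi = sub
            pre = preselection_frequencies(library, sub, replicate=rep)
            post = simulate_selection(pre, truth)
            tables: dict[str, FrequencyTable] = {}
            for c_idx, freqs in ((0, pre), (1, post)):
                seed = config.derived_seed(2, rep, s_idx, c_idx)
                reads = simulate_reads(
                    freqs, library, sub,
                    depth=config.depth, error_rate=config.error_rate, seed=seed,
                )
                table = count_readset(
                    reads,
                    library.sublibrary_cds(sub),
                    offset=lo,
                    full_wt_protein=library.wt_protein,
                )
                count_tables.append(table)
                tables[freqs.condition] = normalize_cpm(table, pseudocount=config.pseudocount)
            parts.append(
                compute_fitness(tables["selected"], tables["unselected"], log_base=config.log_base)
            )
        replicate_landscapes.append(concat_landscapes(parts))

    landscape = average_replicates(replicate_landscapes)
    selection = select_functional_residues(landscape, k=config.k, m=config.m, sided=config.sided)
    recovery = _recovery_stats(landscape, truth)

    cfg_payload = json.loads(config.to_json())
    cfg_payload.pop("outdir", None)  # run location is not part of the science
    report = {
        "config": cfg_payload,
        "config_hash": config.config_hash,
        "n_variants": library.n_variants,
        "discard_tallies": {
            f"{t.condition}_rep{t.replicate}_{t.sublibrary}": t.discarded for t in count_tables
        },
        "mu": selection.mu,
        "sigma": selection.sigma,
        "n_selected": len(selection.selected_positions),
        "selected_positions": sorted(selection.selected_positions),
        "recovery": recovery,
        "position_means": position_summary(landscape).to_dict(),
    }
    run = SyntheticRun(
        config=config,
        wt_cds=wt_cds,
        truth=truth,
        count_tables=count_tables,
        replicate_landscapes=replicate_landscapes,
        landscape=landscape,
        selection=selection,
        report=report,
    )
    if write_outputs and config.outdir:
        _write_run_outputs(run)
    return run


def _write_run_outputs(run: SyntheticRun) -> None:
    outdir = Path(run.config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    h = run.config.config_hash
    counts_to_tsv(outdir / "counts.tsv", run.count_tables, config_hash=h)
    write_landscape_tsv(outdir / "landscape.tsv", run.landscape)
    write_scores_csv(outdir / "scores.csv", run.landscape)
    export_heatmap_matrix(run.landscape, outdir / "heatmap_matrix.tsv", config_hash=h)
    sel = run.selection
    pd.DataFrame(
        {
            "position": sorted(sel.qualifying_counts),
            "qualifying_mutations": [sel.qualifying_counts[p] for p in sorted(sel.qualifying_counts)],
            "selected": [p in sel.selected_positions for p in sorted(sel.qualifying_counts)],
        }
    ).to_csv(outdir / "selection.tsv", sep="\t", index=False)
    (outdir / "run_report.json").write_text(json.dumps(run.report, indent=2, sort_keys=True))
    logger.info("run %s: mu=%.4f sigma=%.4f selected=%d", h, sel.mu, sel.sigma, run.report["n_selected"])


def run_pipeline(config: RunConfig, stages: list[str] | None = None) -> dict:
    """Execute the requested stages in dependency order on the output directory.

    Later stages read earlier stages' TSV outputs, so a subset such as
    ``["fitness", "select"]`` reruns on existing count tables; a missing
    dependency output raises an error naming the stage that must run first.
    """
    stages = list(stages) if stages is not None else list(STAGES)
    unknown = set(stages) - set(STAGES)
    if unknown:
        raise ValueError(f"unknown stages: {sorted(unknown)}")
    if config.outdir is None:
        raise ValueError("run_pipeline requires config.outdir")
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    wt_cds = random_wt_cds(config.n_positions, seed=config.derived_seed(0))
    library = generate_nns_library(wt_cds)

    if "simulate" in stages or "count" in stages:
        # simulate and count are fused: reads exist only in memory, counts are
        # the first durable artifact
        run = run_synthetic_experiment(
            dataclasses.replace(config, outdir=None), write_outputs=False
        )
        counts_to_tsv(outdir / "counts.tsv", run.count_tables, config_hash=config.config_hash)
        (outdir / "truth.json").write_text(
            json.dumps({f"{p}:{s}": v for (p, s), v in run.truth.effects.items()}, sort_keys=True)
        )
    if "fitness" in stages:
        counts_path = outdir / "counts.tsv"
        if not counts_path.exists():
            raise FileNotFoundError("fitness stage needs counts.tsv; run the count stage first")
        tables = counts_from_tsv(counts_path, library.wt_protein)
        reps: dict[int, dict[str, list[FrequencyTable]]] = {}
        for t in tables:
            reps.setdefault(t.replicate, {}).setdefault(t.condition, []).append(
                normalize_cpm(t, pseudocount=config.pseudocount)
            )
        landscapes = []
        for rep, conds in sorted(reps.items()):
            parts = []
            sel_by_sub = {f.sublibrary: f for f in conds["selected"]}
            for unsel in conds["unselected"]:
                parts.append(
                    compute_fitness(sel_by_sub[unsel.sublibrary], unsel, log_base=config.log_base)
                )
            landscapes.append(concat_landscapes(parts))
        landscape = average_replicates(landscapes)
        write_landscape_tsv(outdir / "landscape.tsv", landscape)
        write_scores_csv(outdir / "scores.csv", landscape)
        export_heatmap_matrix(landscape, outdir / "heatmap_matrix.tsv", config_hash=config.config_hash)
    if "select" in stages:
        if not (outdir / "heatmap_matrix.tsv").exists():
            raise FileNotFoundError("select stage needs heatmap_matrix.tsv; run the fitness stage first")
        positions, values, na = read_heatmap_matrix(outdir / "heatmap_matrix.tsv")
        landscape = FitnessLandscape(
            positions=positions,
            wt_protein=library.wt_protein,
            delta_e=values,
            na_mask=na,
            replicate="mean",
        )
        sel = select_functional_residues(landscape, k=config.k, m=config.m, sided=config.sided)
        pd.DataFrame(
            {
                "position": sorted(sel.qualifying_counts),
                "qualifying_mutations": [sel.qualifying_counts[p] for p in sorted(sel.qualifying_counts)],
                "selected": [p in sel.selected_positions for p in sorted(sel.qualifying_counts)],
            }
        ).to_csv(outdir / "selection.tsv", sep="\t", index=False)
    report = {"config_hash": config.config_hash, "stages": stages}
    (outdir / "pipeline_report.json").write_text(json.dumps(report, indent=2, sort_keys=True))
    return report
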
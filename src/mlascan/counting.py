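"""Amplicon read filtering, orientation, translation and variant counting.

Mirrors the counting stage of an NNS deep-mutational-scanning experiment:
merged reads are filtered to the exact amplicon length, oriented against the
wild-type coding sequence, translated, and tallied per (position, amino
acid). Reads with zero protein mismatches count as wild type; reads with two
or more are discarded as multi-mutants (the library is single-mutant by
construction, so a second mutation is treated as sequencing loss).

``orient_and_translate`` is the single-read reference implementation;
``translate_reads`` is a vectorized batch path with identical semantics used
by the pipeline for full-depth experiments.
"""

from __future__ import annotations

import logging

import numpy as np
from Bio.Seq import Seq

from .alphabet import (
    AA_BYTE_TO_INDEX,
    COMPLEMENT_BYTE,
    N_SYMBOLS,
    reads_to_matrix,
    seq_to_bytes,
    translate_matrix,
)
from .synthetic import ReadSet
from .tables import CountTable, FrequencyTable, wt_cell_mask

logger = logging.getLogger(__name__)


def preprocess_reads(reads: ReadSet, expected_length: int) -> ReadSet:
    """Retain only reads of exactly the expected amplicon length.

    The discard tally (reason ``length``) is carried on the returned set;
    indels and truncated merges are removed here since downstream counting
    assumes a fixed frame.
    """
    if expected_length <= 0:
        raise ValueError("expected_length must be positive")
    kept = [r for r in reads.reads if len(r) == expected_length]
    n_discarded = len(reads.reads) - len(kept)
    if not reads.reads:
        logger.warning("preprocess_reads: empty input read set")
    discarded = dict(reads.discarded)
    discarded["length"] = discarded.get("length", 0) + n_discarded
    return ReadSet(
        reads=kept,
        condition=reads.condition,
        replicate=reads.replicate,
        sublibrary=reads.sublibrary,
        seed=reads.seed,
        discarded=discarded,
    )


def orient_and_translate(read: str, wt_cds: str) -> str | None:
    """Translate a read in the orientation closest to the wild-type amplicon.

    Whichever of the read and its reverse complement has the smaller
    nucleotide Hamming distance to ``wt_cds`` is translated; stop codons
    render as ``*``. A tie between the two orientations is ambiguous and
    returns ``None`` (caller tallies the discard).
    """
    if len(read) != len(wt_cds):
        raise ValueError("read length does not match the wild-type amplicon")
    if len(read) % 3:
        raise ValueError("read length not divisible by 3")
    read = read.upper()
    rc = str(Seq(read).reverse_complement())
    d_fwd = sum(a != b for a, b in zip(read, wt_cds))
    d_rev = sum(a != b for a, b in zip(rc, wt_cds))
    if d_fwd == d_rev:
        return None
    oriented = read if d_fwd < d_rev else rc
    return str(Seq(oriented).translate())


def translate_reads(reads: list[str], wt_cds: str) -> tuple[np.ndarray, int]:
    """Vectorized orientation + translation of equal-length reads.

    Returns an (n_kept, L) ASCII amino-acid byte matrix and the number of
    reads discarded for an orientation tie. Semantics match
    :func:`orient_and_translate` read by read.
    """
    if not reads:
        return np.empty((0, len(wt_cds) // 3), dtype=np.uint8), 0
    mat = reads_to_matrix([r.upper() for r in reads])
    if mat.shape[1] != len(wt_cds):
        raise ValueError("read length does not match the wild-type amplicon")
    wt = seq_to_bytes(wt_cds.upper())
    rc = COMPLEMENT_BYTE[mat][:, ::-1]
    d_fwd = (mat != wt).sum(axis=1)
    d_rev = (rc != wt).sum(axis=1)
    tie = d_fwd == d_rev
    oriented = np.where((d_fwd < d_rev)[:, None], mat, rc)[~tie]
    return translate_matrix(oriented), int(tie.sum())


def count_variants(
    proteins: list[str] | np.ndarray,
    wt_protein: str,
    offset: int = 1,
    full_wt_protein: str | None = None,
) -> CountTable:
    """Tally single-mutant proteins into a (position, symbol) count table.

    ``proteins`` are translations of a sub-library amplicon whose first
    residue is position ``offset`` (1-based) of the full-length protein;
    ``wt_protein`` is the matching wild-type segment. Zero mismatches count
    as wild type, exactly one increments the matching cell, two or more are
    discarded as ``multi_mutant``, and symbols outside the 21-letter alphabet
    are discarded as ``ambiguous``.
    """
    if isinstance(proteins, np.ndarray):
        mat = proteins
    else:
        mat = reads_to_matrix(list(proteins)) if len(proteins) else np.empty((0, len(wt_protein)), dtype=np.uint8)
    seg_len = len(wt_protein)
    if mat.size and mat.shape[1] != seg_len:
        raise ValueError("protein length does not match the wild-type segment")
    positions = np.arange(offset, offset + seg_len, dtype=np.int64)
    full_wt = full_wt_protein if full_wt_protein is not None else ("X" * (offset - 1)) + wt_protein
    counts = np.zeros((seg_len, N_SYMBOLS), dtype=np.int64)
    discarded = {"length": 0, "frame": 0, "multi_mutant": 0, "ambiguous": 0}
    wt_count = 0
    if mat.size:
        wt = seq_to_bytes(wt_protein)
        # reads containing any out-of-alphabet symbol are ambiguous
        valid = ~(AA_BYTE_TO_INDEX[mat] == 255).any(axis=1)
        discarded["ambiguous"] = int((~valid).sum())
        mat = mat[valid]
        diff = mat != wt
        n_mut = diff.sum(axis=1)
        wt_count = int((n_mut == 0).sum())
        discarded["multi_mutant"] = int((n_mut >= 2).sum())
        singles = n_mut == 1
        if singles.any():
            rows = np.argmax(diff[singles], axis=1)
            syms = AA_BYTE_TO_INDEX[mat[singles, rows]]
            np.add.at(counts, (rows, syms.astype(np.int64)), 1)
    return CountTable(
        positions=positions,
        wt_protein=full_wt,
        counts=counts,
        wt_count=wt_count,
        discarded=discarded,
    )


def normalize_cpm(table: CountTable, pseudocount: float = 1.0) -> FrequencyTable:
    """Counts-per-million with a uniform pseudocount on every variant cell.

    The pseudocount is added to each of the 20 variant cells per position and
    to the wild-type tally before normalizing the grand total to 1e6;
    wild-type identity cells stay structurally zero. A pseudocount of 0
    reproduces raw CPM (zero cells stay zero and are masked downstream).
    """
    if pseudocount < 0:
        raise ValueError("pseudocount must be non-negative")
    if table.n_retained == 0 and pseudocount == 0:
        raise ValueError("cannot normalize an all-zero count table without a pseudocount")
    wt_cells = wt_cell_mask(table.positions, table.wt_protein)
    smoothed = table.counts.astype(np.float64) + pseudocount
    smoothed[wt_cells] = 0.0
    wt_smoothed = table.wt_count + pseudocount
    total = smoothed.sum() + wt_smoothed
    if total <= 0:
        raise ValueError("no mass to normalize")
    return FrequencyTable(
        positions=table.positions.copy(),
        wt_protein=table.wt_protein,
        cpm=smoothed * (1e6 / total),
        wt_cpm=wt_smoothed * (1e6 / total),
        condition=table.condition,
        replicate=table.replicate,
        sublibrary=table.sublibrary,
    )


def count_readset(
    reads: ReadSet,
    wt_cds_segment: str,
    offset: int = 1,
    full_wt_protein: str | None = None,
) -> CountTable:
    """Length-filter, orient, translate and count one read set.

    Convenience wrapper chaining :func:`preprocess_reads`,
    :func:`translate_reads` and :func:`count_variants`; all discard tallies
    are merged onto the returned table.
    """
    filtered = preprocess_reads(reads, expected_length=len(wt_cds_segment))
    proteins, n_ties = translate_reads(filtered.reads, wt_cds_segment)
    wt_segment = str(Seq(wt_cds_segment).translate())
    table = count_variants(proteins, wt_segment, offset=offset, full_wt_protein=full_wt_protein)
    table.discarded["length"] += filtered.discarded.get("length", 0)
    table.discarded["ambiguous"] += n_ties
    table.condition = reads.condition
    table.replicate = reads.replicate
    table.sublibrary = reads.sublibrary
    return table
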
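"""Filtered base calls from per-genome allele-count tables.

Converts raw nucleotide counts at aligned positions (one row per genome x
position) into a genomes-x-positions matrix of calls in ``{A, C, G, T, N}``,
applying coverage, strand, allele-frequency and indel-proximity filters to
separate confident calls from ambiguous ones, then genome- and position-level
filters to retain only well-covered core positions.

Coordinates are 0-based half-open internally; 1-based in all files read or
written (stated in file headers).
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import h5py
import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

BASES = "ACGT"
N_CODE = np.int8(4)
_BASE_LOOKUP = {b: np.int8(i) for i, b in enumerate(BASES)}
_CODE_TO_CHAR = np.array(list(BASES) + ["N"])

COUNT_COLUMNS = [
    "genome_id", "chrom", "pos",
    "A_fwd", "C_fwd", "G_fwd", "T_fwd",
    "A_rev", "C_rev", "G_rev", "T_rev",
    "fq", "indel_frac",
]


class InsufficientGenomesError(ValueError):
    """Raised when fewer than two genomes survive filtering."""


@dataclass(frozen=True)
class AlleleCounts:
    """Per-strand nucleotide counts for one genome at one reference position.

    ``fq_score`` is an optional SAMtools-style FQ quality (more negative =
    more confident); ``indel_frac`` is the maximum fraction of reads
    supporting an indel within 3 bp of the position.
    """

    genome_id: str
    position: int
    counts_fwd: tuple
    counts_rev: tuple
    fq_score: Optional[float] = None
    indel_frac: Optional[float] = None

    def __post_init__(self):
        if len(self.counts_fwd) != 4 or len(self.counts_rev) != 4:
            raise ValueError("counts_fwd and counts_rev must each have 4 entries (A,C,G,T)")
        if any(c < 0 for c in self.counts_fwd) or any(c < 0 for c in self.counts_rev):
            raise ValueError("allele counts must be non-negative")
        if self.indel_frac is not None and not 0.0 <= self.indel_frac <= 1.0:
            raise ValueError(f"indel_frac must lie in [0, 1], got {self.indel_frac}")


def _call_bases_array(
    fwd: np.ndarray,
    rev: np.ndarray,
    fq: Optional[np.ndarray],
    indel: Optional[np.ndarray],
    maf_min: float = 0.85,
    strand_min: int = 3,
    fq_max: float = -30.0,
    indel_max: float = 0.33,
    unstranded: bool = False,
) -> np.ndarray:
    """Vectorized base calling. ``fwd``/``rev`` are (..., 4) count arrays.

    Returns int8 codes (0..3 = ACGT, 4 = N). Any ambiguity trigger yields N:
    FQ above threshold (when provided), either strand depth below
    ``strand_min``, major allele frequency below ``maf_min``, indel support
    above ``indel_max`` (when provided), a tie for the major allele, or zero
    coverage. With ``unstranded=True`` the per-strand check uses half of the
    total depth.
    """
    total = fwd + rev
    depth = total.sum(axis=-1)
    order = np.argsort(total, axis=-1)  # ascending; ties keep later index last
    major = order[..., -1]
    major_count = np.take_along_axis(total, major[..., None], axis=-1)[..., 0]
    second_count = np.take_along_axis(total, order[..., -2, None], axis=-1)[..., 0]

    with np.errstate(invalid="ignore", divide="ignore"):
        maf = np.where(depth > 0, major_count / np.maximum(depth, 1), 0.0)

    if unstranded:
        strand_ok = (depth / 2.0 >= strand_min)
    else:
        strand_ok = (fwd.sum(axis=-1) >= strand_min) & (rev.sum(axis=-1) >= strand_min)

    ambiguous = (
        (depth == 0)
        | (major_count == second_count)  # tied major allele
        | ~strand_ok
        | (maf < maf_min)
    )
    if fq is not None:
        ambiguous |= np.asarray(fq) > fq_max
    if indel is not None:
        ambiguous |= np.asarray(indel) > indel_max

    calls = major.astype(np.int8)
    calls[ambiguous] = N_CODE
    return calls


def call_base(
    counts: AlleleCounts,
    maf_min: float = 0.85,
    strand_min: int = 3,
    fq_max: float = -30.0,
    indel_max: float = 0.33,
) -> str:
    """Call the consensus base for a single genome/position.

    Returns the major-allele nucleotide, or ``"N"`` when any ambiguity
    trigger fires (see :func:`_call_bases_array`). Pure function: identical
    inputs always give identical output.
    """
    fwd = np.asarray(counts.counts_fwd, dtype=float)[None, :]
    rev = np.asarray(counts.counts_rev, dtype=float)[None, :]
    fq = None if counts.fq_score is None else np.array([counts.fq_score])
    indel = None if counts.indel_frac is None else np.array([counts.indel_frac])
    code = _call_bases_array(
        fwd, rev, fq, indel,
        maf_min=maf_min, strand_min=strand_min, fq_max=fq_max, indel_max=indel_max,
    )[0]
    return str(_CODE_TO_CHAR[code])


@dataclass
class BaseCallMatrix:
    """Genomes x positions matrix of filtered base calls.

    ``calls`` holds int8 codes (0..3 = ACGT, 4 = N); ``positions`` are
    0-based reference coordinates. ``provenance`` is a list of JSON-able
    events recording which filter removed each genome or position.
    """

    genomes: list
    positions: np.ndarray
    calls: np.ndarray
    genome_median_coverage: np.ndarray
    position_median_coverage: np.ndarray
    provenance: list = field(default_factory=list)

    def __post_init__(self):
        self.positions = np.asarray(self.positions, dtype=np.int64)
        self.calls = np.asarray(self.calls, dtype=np.int8)
        if self.calls.shape != (len(self.genomes), self.positions.size):
            raise ValueError("calls shape does not match genomes x positions")

    @property
    def n_genomes(self) -> int:
        return len(self.genomes)

    @property
    def n_positions(self) -> int:
        return self.positions.size

    def calls_char(self) -> np.ndarray:
        """Calls as single-character strings."""
        return _CODE_TO_CHAR[self.calls]

    def genome_index(self, genome_id: str) -> int:
        return self.genomes.index(genome_id)

    def subset(self, genomes: Sequence[str]) -> "BaseCallMatrix":
        """Row subset (no re-filtering)."""
        idx = [self.genome_index(g) for g in genomes]
        return BaseCallMatrix(
            genomes=list(genomes),
            positions=self.positions.copy(),
            calls=self.calls[idx],
            genome_median_coverage=self.genome_median_coverage[idx],
            position_median_coverage=self.position_median_coverage.copy(),
            provenance=list(self.provenance) + [{"event": "subset", "genomes": list(genomes)}],
        )

    # --- serialization ----------------------------------------------------

    def to_hdf5(self, path) -> None:
        with h5py.File(path, "w") as f:
            f.attrs["format"] = "clademix-basecalls-v1"
            f.attrs["coordinates"] = "0-based half-open"
            f.attrs["provenance"] = json.dumps(self.provenance)
            f.create_dataset(
                "genomes", data=np.array(self.genomes, dtype="S"), track_times=False
            )
            f.create_dataset("positions", data=self.positions, track_times=False)
            f.create_dataset("calls", data=self.calls, track_times=False)
            f.create_dataset(
                "genome_median_coverage", data=self.genome_median_coverage, track_times=False
            )
            f.create_dataset(
                "position_median_coverage", data=self.position_median_coverage, track_times=False
            )

    @classmethod
    def from_hdf5(cls, path) -> "BaseCallMatrix":
        with h5py.File(path, "r") as f:
            if f.attrs.get("format") != "clademix-basecalls-v1":
                raise ValueError(f"{path} is not a clademix base-call matrix")
            return cls(
                genomes=[g.decode() for g in f["genomes"][:]],
                positions=f["positions"][:],
                calls=f["calls"][:],
                genome_median_coverage=f["genome_median_coverage"][:],
                position_median_coverage=f["position_median_coverage"][:],
                provenance=json.loads(f.attrs["provenance"]),
            )

    def to_tsv(self, path) -> None:
        """TSV export: one row per genome, one column per position (1-based)."""
        with open(path, "w") as fh:
            fh.write("# clademix base-call matrix; positions are 1-based\n")
            fh.write("genome_id\t" + "\t".join(str(p + 1) for p in self.positions) + "\n")
            chars = self.calls_char()
            for i, g in enumerate(self.genomes):
                fh.write(g + "\t" + "\t".join(chars[i]) + "\n")


def _counts_to_arrays(all_counts) -> tuple:
    """Normalize input (DataFrame or iterable of AlleleCounts) to dense arrays."""
    if isinstance(all_counts, pd.DataFrame):
        df = all_counts
    else:
        rows = []
        for c in all_counts:
            rows.append(
                (c.genome_id, "ref", c.position, *c.counts_fwd, *c.counts_rev,
                 np.nan if c.fq_score is None else c.fq_score,
                 np.nan if c.indel_frac is None else c.indel_frac)
            )
        df = pd.DataFrame(rows, columns=COUNT_COLUMNS)
    genomes = sorted(df["genome_id"].unique().tolist())
    positions = np.sort(df["pos"].unique())
    g_idx = df["genome_id"].map({g: i for i, g in enumerate(genomes)}).to_numpy()
    p_idx = np.searchsorted(positions, df["pos"].to_numpy())
    G, P = len(genomes), positions.size
    fwd = np.zeros((G, P, 4))
    rev = np.zeros((G, P, 4))
    fwd[g_idx, p_idx] = df[["A_fwd", "C_fwd", "G_fwd", "T_fwd"]].to_numpy()
    has_rev = {"A_rev", "C_rev", "G_rev", "T_rev"} <= set(df.columns)
    if has_rev:
        rev[g_idx, p_idx] = df[["A_rev", "C_rev", "G_rev", "T_rev"]].to_numpy()
    fq = None
    if "fq" in df.columns and df["fq"].notna().any():
        fq = np.full((G, P), -np.inf)  # missing FQ never triggers ambiguity
        vals = df["fq"].to_numpy(dtype=float)
        ok = np.isfinite(vals)
        fq[g_idx[ok], p_idx[ok]] = vals[ok]
    indel = None
    if "indel_frac" in df.columns and df["indel_frac"].notna().any():
        indel = np.zeros((G, P))
        vals = df["indel_frac"].to_numpy(dtype=float)
        ok = np.isfinite(vals)
        indel[g_idx[ok], p_idx[ok]] = vals[ok]
    return genomes, positions, fwd, rev, fq, indel, has_rev


def build_matrix(
    all_counts,
    genome_cov_min: float = 8.0,
    pos_ambig_max: float = 0.10,
    pos_cov_min: float = 5.0,
    pos_cov_copy_mult: float = 2.0,
    genome_ambig_max: float = 0.10,
    maf_min: float = 0.85,
    strand_min: int = 3,
    fq_max: float = -30.0,
    indel_max: float = 0.33,
) -> BaseCallMatrix:
    """Build a filtered :class:`BaseCallMatrix` from allele-count tables.

    Filters are applied in a fixed order:

    1. drop genomes whose median coverage across all positions is below
       ``genome_cov_min``;
    2. call bases per genome/position (ambiguity triggers -> N), using only
       genomes surviving step 1;
    3. drop positions with an N fraction above ``pos_ambig_max``, median
       coverage below ``pos_cov_min``, or median coverage above
       ``pos_cov_copy_mult`` times the median coverage of core positions
       (core = positions passing the N-fraction filter) — a copy-number
       proxy;
    4. drop genomes with an N fraction above ``genome_ambig_max`` among the
       retained positions.

    Raises :class:`InsufficientGenomesError` if fewer than two genomes
    survive. A provenance log records every removal.
    """
    genomes, positions, fwd, rev, fq, indel, has_rev = _counts_to_arrays(all_counts)
    if len(genomes) < 2:
        raise InsufficientGenomesError("need at least 2 genomes")
    provenance = [{
        "event": "build_matrix",
        "params": {
            "genome_cov_min": genome_cov_min, "pos_ambig_max": pos_ambig_max,
            "pos_cov_min": pos_cov_min, "pos_cov_copy_mult": pos_cov_copy_mult,
            "genome_ambig_max": genome_ambig_max, "maf_min": maf_min,
            "strand_min": strand_min, "fq_max": fq_max, "indel_max": indel_max,
        },
        "coordinates": "0-based half-open",
    }]
    unstranded = not has_rev
    if unstranded:
        warnings.warn(
            "no reverse-strand counts supplied; applying the per-strand depth "
            "filter to total/2", stacklevel=2,
        )
        provenance.append({"event": "warning", "message": "unstranded counts; strand filter uses total/2"})
    if fq is None:
        warnings.warn("no FQ scores supplied; skipping the FQ ambiguity trigger", stacklevel=2)
        provenance.append({"event": "warning", "message": "FQ scores absent; FQ trigger skipped"})

    depth = (fwd + rev).sum(axis=-1)  # G x P

    # step 1: genome median coverage
    g_median = np.median(depth, axis=1)
    keep_g = g_median >= genome_cov_min
    for g, m in zip(genomes, g_median):
        if m < genome_cov_min:
            provenance.append({"event": "drop_genome", "genome": g,
                               "filter": "median_coverage", "value": float(m)})
    genomes = [g for g, k in zip(genomes, keep_g) if k]
    if len(genomes) < 2:
        raise InsufficientGenomesError("fewer than 2 genomes survive the coverage filter")
    fwd, rev, depth = fwd[keep_g], rev[keep_g], depth[keep_g]
    fq = fq[keep_g] if fq is not None else None
    indel = indel[keep_g] if indel is not None else None

    # step 2: base calls on surviving genomes only
    calls = _call_bases_array(
        fwd, rev, fq, indel,
        maf_min=maf_min, strand_min=strand_min, fq_max=fq_max, indel_max=indel_max,
        unstranded=unstranded,
    )

    # step 3: position filters
    n_frac = (calls == N_CODE).mean(axis=0)
    core = n_frac <= pos_ambig_max
    p_median = np.median(depth, axis=0)
    core_median = np.median(p_median[core]) if core.any() else 0.0
    keep_p = core & (p_median >= pos_cov_min) & (p_median <= pos_cov_copy_mult * core_median)
    for j in np.flatnonzero(~keep_p):
        if not core[j]:
            why = "n_fraction"
            val = float(n_frac[j])
        elif p_median[j] < pos_cov_min:
            why = "low_coverage"
            val = float(p_median[j])
        else:
            why = "copy_number"
            val = float(p_median[j])
        provenance.append({"event": "drop_position", "pos": int(positions[j]),
                           "filter": why, "value": val})
    positions = positions[keep_p]
    calls = calls[:, keep_p]
    depth = depth[:, keep_p]

    # step 4: genome N fraction among retained positions
    if positions.size:
        g_nfrac = (calls == N_CODE).mean(axis=1)
    else:
        g_nfrac = np.zeros(len(genomes))
    keep_g2 = g_nfrac <= genome_ambig_max
    for g, f, k in zip(genomes, g_nfrac, keep_g2):
        if not k:
            provenance.append({"event": "drop_genome", "genome": g,
                               "filter": "n_fraction", "value": float(f)})
    genomes = [g for g, k in zip(genomes, keep_g2) if k]
    calls = calls[keep_g2]
    depth = depth[keep_g2]
    if len(genomes) < 2:
        raise InsufficientGenomesError("fewer than 2 genomes survive the ambiguity filter")

    n_poly = int(
        sum(np.unique(col[col != N_CODE]).size >= 2 for col in calls.T)
    )
    if n_poly == 0:
        provenance.append({"event": "note", "message": "no polymorphic positions after filtering"})
    provenance.append({"event": "summary", "n_genomes": len(genomes),
                       "n_positions": int(positions.size), "n_polymorphic": n_poly})
    return BaseCallMatrix(
        genomes=genomes,
        positions=positions,
        calls=calls,
        genome_median_coverage=np.median(depth, axis=1) if positions.size else np.zeros(len(genomes)),
        position_median_coverage=np.median(depth, axis=0) if len(genomes) else np.zeros(0),
        provenance=provenance,
    )


def polymorphic_positions(matrix: BaseCallMatrix) -> np.ndarray:
    """Positions where at least two distinct non-N calls occur."""
    keep = np.zeros(matrix.n_positions, dtype=bool)
    for j in range(matrix.n_positions):
        col = matrix.calls[:, j]
        keep[j] = np.unique(col[col != N_CODE]).size >= 2
    return matrix.positions[keep]


def hamming_distances(matrix: BaseCallMatrix, n_policy: str = "mismatch") -> pd.DataFrame:
    """Pairwise Hamming distances between genomes over retained positions.

    ``n_policy="mismatch"`` (default) counts any pair where either call is N
    as a difference; ``"ignore"`` skips positions with an N in either genome.
    The result is a symmetric DataFrame with a zero diagonal.
    """
    if n_policy not in ("mismatch", "ignore"):
        raise ValueError(f"unknown n_policy {n_policy!r}")
    calls = matrix.calls
    G = matrix.n_genomes
    dist = np.zeros((G, G), dtype=np.int64)
    for i in range(G):
        diff = calls[i] != calls[i + 1:]
        if n_policy == "mismatch":
            # N vs base call counts as a difference; N vs N does not, which
            # keeps the self-distance at zero
            one_n = (calls[i] == N_CODE) ^ (calls[i + 1:] == N_CODE)
            d = (diff | one_n).sum(axis=1)
        else:
            either_n = (calls[i] == N_CODE) | (calls[i + 1:] == N_CODE)
            d = (diff & ~either_n).sum(axis=1)
        dist[i, i + 1:] = d
        dist[i + 1:, i] = d
    return pd.DataFrame(dist, index=matrix.genomes, columns=matrix.genomes)


# --- count-table IO -------------------------------------------------------

def read_counts_tsv(path) -> pd.DataFrame:
    """Read an allele-count table (TSV; ``pos`` 1-based on disk -> 0-based)."""
    df = pd.read_csv(path, sep="\t", comment="#")
    missing = {"genome_id", "pos", "A_fwd", "C_fwd", "G_fwd", "T_fwd"} - set(df.columns)
    if missing:
        raise ValueError(f"count table {path} is missing columns: {sorted(missing)}")
    df = df.copy()
    df["pos"] = df["pos"].astype(np.int64) - 1
    if "chrom" not in df.columns:
        df["chrom"] = "ref"
    return df


def write_counts_tsv(df: pd.DataFrame, path) -> None:
    """Write an allele-count table (``pos`` converted 0-based -> 1-based)."""
    out = df.copy()
    out["pos"] = out["pos"].astype(np.int64) + 1
    with open(path, "w") as fh:
        fh.write("# clademix allele counts; pos is 1-based\n")
        out.to_csv(fh, sep="\t", index=False)
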
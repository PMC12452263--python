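"""Clade discovery on a species phylogeny and clade-specific allele catalogs.

A clade is the set of genomes descending from one branch of the species
phylogeny. For each candidate clade we catalog clade-specific alleles
(csSNVs): alleles unanimous among the clade's genomes (ignoring ambiguous
calls) and absent from every genome outside the clade. These markers are
what the classifier counts in a metagenome.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import dendropy
import h5py
import numpy as np
import pandas as pd

from .basecalls import BaseCallMatrix, N_CODE, _CODE_TO_CHAR

__all__ = [
    "PhylogenyModel",
    "CladeDefinition",
    "DatabaseParams",
    "ReferenceDatabase",
    "scale_tree",
    "discover_clades",
    "find_cs_alleles",
    "build_database",
]


@dataclass
class PhylogenyModel:
    """A rooted species phylogeny with branch lengths and bootstrap supports.

    ``snv_scaled`` records whether branch lengths are in core-genome SNV
    units (after :func:`scale_tree`); clade discovery's branch-length
    threshold is meant to be applied on an SNV-scaled tree.
    """

    tree: dendropy.Tree
    snv_scaled: bool = False

    @classmethod
    def from_newick(cls, source: str, snv_scaled: bool = False) -> "PhylogenyModel":
        """Parse a Newick/NEXUS tree from a path or a literal string.

        Bootstrap values may appear as internal-node labels or as numeric
        node comments; both dialects are handled (auto-detected per node).
        """
        kwargs = dict(preserve_underscores=True, suppress_internal_node_taxa=True)
        if isinstance(source, str) and source.lstrip().startswith("("):
            schema = "nexus" if source.lstrip().lower().startswith("#nexus") else "newick"
            tree = dendropy.Tree.get(data=source, schema=schema, **kwargs)
        else:
            text = open(source).read()
            schema = "nexus" if text.lstrip().lower().startswith("#nexus") else "newick"
            tree = dendropy.Tree.get(data=text, schema=schema, **kwargs)
        return cls(tree=tree, snv_scaled=snv_scaled)

    def to_newick(self) -> str:
        return self.tree.as_string(schema="newick", suppress_rooting=True).strip()

    def tip_labels(self) -> list:
        return [leaf.taxon.label for leaf in self.tree.leaf_node_iter()]

    def clone(self) -> "PhylogenyModel":
        return PhylogenyModel(tree=self.tree.clone(depth=1), snv_scaled=self.snv_scaled)


def _node_support(node: dendropy.Node) -> Optional[float]:
    """Bootstrap support of an internal node, normalized to [0, 1]."""
    candidates = []
    if node.label is not None:
        candidates.append(node.label)
    candidates.extend(getattr(node, "comments", []) or [])
    for text in candidates:
        try:
            v = float(str(text).strip("[]&"))
        except ValueError:
            continue
        return v / 100.0 if v > 1.0 else v
    return None


@dataclass(frozen=True)
class CladeDefinition:
    """One phylogeny branch's clade and (once found) its marker alleles.

    ``cs_alleles`` is a list of ``(position, allele_code)`` pairs
    (0-based positions, codes 0..3 = ACGT); ``None`` until
    :func:`find_cs_alleles` has run. ``passed`` flags whether the clade
    retained at least ``min_cssnvs`` markers.
    """

    clade_id: str
    members: frozenset
    branch_length: Optional[float] = None
    bootstrap: Optional[float] = None
    cs_alleles: Optional[tuple] = None
    passed: Optional[bool] = None

    @property
    def n_cs(self) -> int:
        return 0 if self.cs_alleles is None else len(self.cs_alleles)

    def positions(self) -> np.ndarray:
        return np.array([p for p, _ in (self.cs_alleles or ())], dtype=np.int64)

    def alleles(self) -> np.ndarray:
        return np.array([a for _, a in (self.cs_alleles or ())], dtype=np.int8)


def scale_tree(model: PhylogenyModel, dist: pd.DataFrame, r_min: float = 0.75) -> PhylogenyModel:
    """Rescale branch lengths into core-genome SNV units.

    Computes the Pearson correlation between patristic distances and the
    Hamming distances in ``dist`` over all tip pairs. If r exceeds
    ``r_min``, every branch length is multiplied by the least-squares slope
    through the origin of (patristic -> Hamming) and ``snv_scaled`` is set;
    otherwise the tree is returned unchanged with a warning. Topology is
    never altered.
    """
    from scipy.stats import pearsonr

    tips = model.tip_labels()
    if len(tips) < 3:
        raise ValueError("tree scaling requires at least 3 tips")
    missing = set(tips) - set(dist.index)
    if missing:
        raise ValueError(f"tips absent from the distance matrix: {sorted(missing)}")
    pdm = model.tree.phylogenetic_distance_matrix()
    taxa = {t.label: t for t in model.tree.taxon_namespace if t.label in set(tips)}
    pat, ham = [], []
    for i in range(len(tips)):
        for j in range(i + 1, len(tips)):
            pat.append(pdm.patristic_distance(taxa[tips[i]], taxa[tips[j]]))
            ham.append(float(dist.loc[tips[i], tips[j]]))
    pat = np.asarray(pat)
    ham = np.asarray(ham)
    if np.std(pat) == 0 or np.std(ham) == 0:
        r = np.nan
    else:
        r = pearsonr(pat, ham)[0]
    if not np.isfinite(r) or r <= r_min:
        warnings.warn(
            f"patristic vs SNV distance correlation r={r:.3f} is not above "
            f"{r_min}; branch lengths left unscaled", stacklevel=2,
        )
        out = model.clone()
        out.snv_scaled = False
        return out
    slope = float(np.sum(pat * ham) / np.sum(pat * pat))
    out = model.clone()
    for edge in out.tree.preorder_edge_iter():
        if edge.length is not None:
            edge.length = edge.length * slope
    out.snv_scaled = True
    return out


def discover_clades(
    model: PhylogenyModel,
    min_genomes: int = 3,
    min_branch: float = 1000.0,
    min_bootstrap: float = 0.75,
    manual_clades: Optional[Sequence] = None,
) -> list:
    """Scan every branch for candidate clades.

    A branch qualifies when its clade has at least ``min_genomes`` tips, its
    length is at least ``min_branch`` (SNV units on a scaled tree), and its
    bootstrap support exceeds ``min_bootstrap``. The two branches incident
    to the root are skipped (on a midpoint-rooted tree they would duplicate
    each other's complement). Nested clades are emitted — output is
    hierarchical, not a partition. ``manual_clades`` (iterable of
    ``(clade_id, members)``) are appended verbatim.
    """
    if not model.snv_scaled:
        warnings.warn(
            "tree is not SNV-scaled; the min_branch threshold is applied in "
            "raw tree units", stacklevel=2,
        )
    supports = [
        _node_support(nd)
        for nd in model.tree.preorder_internal_node_iter()
        if nd is not model.tree.seed_node
    ]
    no_support_anywhere = all(s is None for s in supports)
    if no_support_anywhere and supports:
        warnings.warn(
            "tree carries no bootstrap supports; treating every branch as "
            "fully supported", stacklevel=2,
        )
    clades = []
    idx = 0
    root = model.tree.seed_node
    for nd in model.tree.preorder_internal_node_iter():
        if nd is root or nd.parent_node is root:
            continue  # root-incident branches are skipped
        members = frozenset(leaf.taxon.label for leaf in nd.leaf_iter())
        if len(members) < min_genomes:
            continue
        length = nd.edge.length or 0.0
        if length < min_branch:
            continue
        support = _node_support(nd)
        if support is None:
            if not no_support_anywhere:
                continue
            support = 1.0
        if support <= min_bootstrap:
            continue
        idx += 1
        clades.append(CladeDefinition(
            clade_id=f"clade_{idx:04d}",
            members=members,
            branch_length=float(length),
            bootstrap=float(support),
        ))
    for cid, members in (manual_clades or []):
        clades.append(CladeDefinition(clade_id=str(cid), members=frozenset(members)))
    return clades


def find_cs_alleles(
    matrix: BaseCallMatrix,
    clade: CladeDefinition,
    ambig_max: float = 0.10,
    outgroup_calls: Optional[BaseCallMatrix] = None,
    outgroup_max: float = 0.10,
    min_cssnvs: int = 10,
) -> CladeDefinition:
    """Catalog the clade-specific alleles of one clade.

    A position contributes a marker when (1) all in-clade genomes with a
    non-ambiguous call agree on the allele, (2) fewer than ``ambig_max`` of
    in-clade genomes are ambiguous there, and (3) the allele is found in no
    genome outside the clade (at least one outside genome must carry a
    different, non-ambiguous call — otherwise the site is not a marker of
    anything). When ``outgroup_calls`` is given (genomes of *other* species
    that recruit reads), positions where more than ``outgroup_max`` of
    outgroup genomes have any non-ambiguous call are discarded entirely.

    Returns the clade with ``cs_alleles`` filled in and ``passed`` set to
    ``n_cs >= min_cssnvs``.
    """
    missing = clade.members - set(matrix.genomes)
    if missing:
        raise ValueError(f"clade members absent from matrix: {sorted(missing)}")
    g_index = {g: i for i, g in enumerate(matrix.genomes)}
    in_idx = np.array(sorted(g_index[g] for g in clade.members))
    out_idx = np.array([i for i in range(matrix.n_genomes) if i not in set(in_idx)], dtype=int)

    in_calls = matrix.calls[in_idx]
    in_nonN = in_calls != N_CODE
    n_frac = 1.0 - in_nonN.mean(axis=0)
    # unanimity among non-N members: min == max over non-N calls
    lo = np.where(in_nonN, in_calls, np.int8(100)).min(axis=0)
    hi = np.where(in_nonN, in_calls, np.int8(-1)).max(axis=0)
    unanimous = (lo == hi) & in_nonN.any(axis=0)
    allele = lo  # valid where unanimous

    ok = unanimous & (n_frac < ambig_max)
    if out_idx.size:
        out_calls = matrix.calls[out_idx]
        out_nonN = out_calls != N_CODE
        shared = (out_nonN & (out_calls == allele[None, :])).any(axis=0)
        informative = out_nonN.any(axis=0)  # some outside genome must differ
        ok &= informative & ~shared
    else:
        ok &= False

    if outgroup_calls is not None:
        og_pos = {p: j for j, p in enumerate(outgroup_calls.positions)}
        og_frac = np.zeros(matrix.n_positions)
        cols = [og_pos.get(p, -1) for p in matrix.positions]
        has = np.array([c >= 0 for c in cols])
        if has.any():
            sel = np.array([c for c in cols if c >= 0])
            og_nonN = (outgroup_calls.calls[:, sel] != N_CODE).mean(axis=0)
            og_frac[has] = og_nonN
        ok &= og_frac <= outgroup_max

    js = np.flatnonzero(ok)
    cs = tuple((int(matrix.positions[j]), int(allele[j])) for j in js)
    return replace(clade, cs_alleles=cs, passed=len(cs) >= min_cssnvs)


@dataclass(frozen=True)
class DatabaseParams:
    """Construction parameters for a reference database (defaults mirror the
    classifier's recommended settings: ``-n 0.1 -p 0.1``)."""

    min_genomes: int = 3
    min_branch: float = 1000.0
    min_bootstrap: float = 0.75
    ambig_max: float = 0.10          # -n
    outgroup_max: float = 0.10       # -p
    min_cssnvs: int = 10

    def to_dict(self) -> dict:
        return {
            "min_genomes": self.min_genomes, "min_branch": self.min_branch,
            "min_bootstrap": self.min_bootstrap, "ambig_max": self.ambig_max,
            "outgroup_max": self.outgroup_max, "min_cssnvs": self.min_cssnvs,
        }


@dataclass
class ReferenceDatabase:
    """All retained clades plus provenance; serializable to HDF5 and TSV."""

    clades: list
    params: DatabaseParams
    matrix_hash: str
    tree_hash: str
    dropped_clades: list = field(default_factory=list)

    def clade_ids(self) -> list:
        return [c.clade_id for c in self.clades]

    def get(self, clade_id: str) -> CladeDefinition:
        for c in self.clades:
            if c.clade_id == clade_id:
                return c
        raise KeyError(clade_id)

    def informative_positions(self) -> np.ndarray:
        """Sorted union of all clades' marker positions."""
        pos = set()
        for c in self.clades:
            pos.update(p for p, _ in c.cs_alleles)
        return np.array(sorted(pos), dtype=np.int64)

    def minimal_clades(self) -> list:
        """Clades with no other database clade nested inside them.

        These are mutually disjoint (clades are nested or disjoint on a
        tree) and serve as the default non-overlapping set for composition
        summaries.
        """
        out = []
        for c in self.clades:
            if not any(o is not c and o.members < c.members for o in self.clades):
                out.append(c)
        return out

    # --- serialization ----------------------------------------------------

    def save(self, path) -> None:
        with h5py.File(path, "w") as f:
            f.attrs["format"] = "clademix-db-v1"
            f.attrs["coordinates"] = "0-based half-open"
            f.attrs["metadata"] = json.dumps({
                "params": self.params.to_dict(),
                "matrix_hash": self.matrix_hash,
                "tree_hash": self.tree_hash,
                "dropped_clades": self.dropped_clades,
                "clade_order": [c.clade_id for c in self.clades],
            }, sort_keys=True)
            grp = f.create_group("clades")
            for c in self.clades:
                g = grp.create_group(c.clade_id)
                g.attrs["branch_length"] = -1.0 if c.branch_length is None else c.branch_length
                g.attrs["bootstrap"] = -1.0 if c.bootstrap is None else c.bootstrap
                g.create_dataset("members", data=np.array(sorted(c.members), dtype="S"),
                                 track_times=False)
                g.create_dataset("positions", data=c.positions(), track_times=False)
                g.create_dataset("alleles", data=c.alleles(), track_times=False)

    @classmethod
    def load(cls, path) -> "ReferenceDatabase":
        with h5py.File(path, "r") as f:
            if f.attrs.get("format") != "clademix-db-v1":
                raise ValueError(f"{path} is not a clademix reference database")
            meta = json.loads(f.attrs["metadata"])
            clades = []
            for cid in meta["clade_order"]:
                g = f["clades"][cid]
                bl = float(g.attrs["branch_length"])
                bs = float(g.attrs["bootstrap"])
                clades.append(CladeDefinition(
                    clade_id=cid,
                    members=frozenset(m.decode() for m in g["members"][:]),
                    branch_length=None if bl < 0 else bl,
                    bootstrap=None if bs < 0 else bs,
                    cs_alleles=tuple(
                        (int(p), int(a)) for p, a in zip(g["positions"][:], g["alleles"][:])
                    ),
                    passed=True,
                ))
            return cls(
                clades=clades,
                params=DatabaseParams(**meta["params"]),
                matrix_hash=meta["matrix_hash"],
                tree_hash=meta["tree_hash"],
                dropped_clades=meta["dropped_clades"],
            )

    def cs_alleles_tsv(self, path) -> None:
        """TSV export of every clade's markers (positions 1-based)."""
        with open(path, "w") as fh:
            fh.write("# clademix clade-specific alleles; pos is 1-based\n")
            fh.write("clade_id\tpos\tallele\tn_members\n")
            for c in self.clades:
                for p, a in c.cs_alleles:
                    fh.write(f"{c.clade_id}\t{p + 1}\t{_CODE_TO_CHAR[a]}\t{len(c.members)}\n")


def _matrix_hash(matrix: BaseCallMatrix) -> str:
    h = hashlib.sha256()
    h.update(",".join(matrix.genomes).encode())
    h.update(matrix.positions.tobytes())
    h.update(np.ascontiguousarray(matrix.calls).tobytes())
    return h.hexdigest()


def build_database(
    matrix: BaseCallMatrix,
    model: PhylogenyModel,
    params: DatabaseParams = DatabaseParams(),
    outgroup_calls: Optional[BaseCallMatrix] = None,
    manual_clades: Optional[Sequence] = None,
) -> ReferenceDatabase:
    """Discover clades, catalog their markers, and assemble the database.

    Deterministic given identical inputs and parameters; clades failing the
    ``min_cssnvs`` floor are recorded in ``dropped_clades`` (manual clades
    are not exempt). Raises ``ValueError`` when no clade survives.
    """
    tips = set(model.tip_labels())
    extra = tips - set(matrix.genomes)
    if extra:
        raise ValueError(f"tree tips absent from the base-call matrix: {sorted(extra)}")
    candidates = discover_clades(
        model, min_genomes=params.min_genomes, min_branch=params.min_branch,
        min_bootstrap=params.min_bootstrap, manual_clades=manual_clades,
    )
    kept, dropped = [], []
    for clade in candidates:
        clade = find_cs_alleles(
            matrix, clade, ambig_max=params.ambig_max,
            outgroup_calls=outgroup_calls, outgroup_max=params.outgroup_max,
            min_cssnvs=params.min_cssnvs,
        )
        (kept if clade.passed else dropped).append(clade)
    if not kept:
        raise ValueError("no clade passed discovery + marker filters; cannot build database")
    return ReferenceDatabase(
        clades=kept,
        params=params,
        matrix_hash=_matrix_hash(matrix),
        tree_hash=hashlib.sha256(model.to_newick().encode()).hexdigest(),
        dropped_clades=[c.clade_id for c in dropped],
    )
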
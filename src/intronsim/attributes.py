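"""The five attributes of a simulated (or reference) sequence set.

For a labelled set of intron-like sequences the pipeline computes

``L_MSA``   number of columns of the multiple sequence alignment,
``R_K2I``   transition/transversion ratio under the Kimura two-parameter
            distance, pooled over all sequence pairs,
``Dbar``    mean pairwise K2P distance over all defined pairs,
``SEDbar``  bootstrap standard error of ``Dbar`` (resampling alignment
            columns with replacement),
``TS_ML``   topology score of the neighbor-joining tree of the set against
            a reference tree: per leaf, one point for matching branch form
            (L-shape / inverted-L / straight in the ladderized drawing) and
            one point for matching relative location (which leaf sits in the
            row immediately above), so at most ``2N`` points in total.

The builtin aligner is a deterministic progressive aligner (k-mer distance
guide tree, integer sum-of-pairs Needleman-Wunsch profile merges with match
+1, mismatch -1, gap -2 per site); ``backend="mafft"`` shells out to MAFFT
when available.  Tree inference is neighbor joining on K2P distances, a
deterministic distance-based stand-in for a full ML search — the scoring
logic, not the tree-search engine, is what the attribute measures.
"""

from __future__ import annotations

import enum
import itertools
import shutil
import subprocess
import tempfile
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import scipy.cluster.hierarchy as sch
import skbio
from skbio import DistanceMatrix

from .core import Sequence, encode, decode
from .tree import GuideTree, LadderLayout, StructureError, TreeNode, ladderize

__all__ = [
    "GAP",
    "TOP",
    "Msa",
    "PairStats",
    "OverallStats",
    "AttributeSet",
    "AttributeConfig",
    "BranchForm",
    "BackendUnavailableError",
    "AttributeUndefinedError",
    "align",
    "pair_stats",
    "overall_stats",
    "sed_bootstrap",
    "k2p_distance_matrix",
    "nj_tree",
    "infer_tree",
    "branch_form",
    "relative_location",
    "topology_score",
    "attribute_set",
]

GAP = 4  # gap code appended to the A/C/G/T codes 0..3
#: Sentinel returned by :func:`relative_location` for the topmost leaf.
TOP = "TOP"

_MATCH = 1
_MISMATCH = -1
_GAP = 2  # per-site gap penalty (applied as a cost)


class BackendUnavailableError(RuntimeError):
    """The requested external aligner is not on PATH (builtin is available)."""


class AttributeUndefinedError(ValueError):
    """No pair of rows yields a defined distance."""


def _encode_gapped(row: str) -> np.ndarray:
    out = np.empty(len(row), dtype=np.uint8)
    for i, ch in enumerate(row):
        out[i] = GAP if ch == "-" else encode(ch)[0]
    return out


def _decode_gapped(codes: np.ndarray) -> str:
    lut = np.frombuffer(b"ACGT-", dtype=np.uint8)
    return lut[codes].tobytes().decode("ascii")


@dataclass
class Msa:
    """A multiple sequence alignment stored as an (n, L) uint8 code matrix."""

    ids: list[str]
    matrix: np.ndarray  # codes 0..3 bases, 4 gap

    def __post_init__(self) -> None:
        if self.matrix.ndim != 2 or len(self.ids) != self.matrix.shape[0]:
            raise ValueError("ids and matrix rows disagree")

    @property
    def n_rows(self) -> int:
        return self.matrix.shape[0]

    @property
    def n_cols(self) -> int:
        return self.matrix.shape[1]

    @property
    def rows(self) -> dict[str, str]:
        return {i: _decode_gapped(r) for i, r in zip(self.ids, self.matrix)}

    def degapped(self, id: str) -> str:
        row = self.matrix[self.ids.index(id)]
        return decode(row[row != GAP])


# ---------------------------------------------------------------------------
# builtin progressive aligner


def _kmer_sets(seqs: list[Sequence], k: int) -> list[set]:
    return [
        {s.bases[i : i + k] for i in range(len(s.bases) - k + 1)} for s in seqs
    ]


def _kmer_distance_condensed(seqs: list[Sequence]) -> np.ndarray:
    k = max(2, min(6, min(len(s) for s in seqs)))
    sets = _kmer_sets(seqs, k)
    n = len(seqs)
    out = np.zeros(n * (n - 1) // 2)
    for idx, (i, j) in enumerate(itertools.combinations(range(n), 2)):
        denom = min(len(sets[i]), len(sets[j]))
        shared = len(sets[i] & sets[j]) if denom else 0
        out[idx] = 1.0 - (shared / denom if denom else 0.0)
    return out


def _profile_counts(matrix: np.ndarray) -> np.ndarray:
    """Per-column base counts, shape (L, 4)."""
    return np.stack([(matrix == b).sum(axis=0) for b in range(4)], axis=1).astype(
        np.int32
    )


def _merge_profiles(
    a: tuple[list[str], np.ndarray], b: tuple[list[str], np.ndarray]
) -> tuple[list[str], np.ndarray]:
    """Global alignment of two profiles under integer sum-of-pairs scoring.

    Scores are summed over sequence pairs (not averaged) so the dynamic
    programme is exact integer arithmetic and the traceback is
    deterministic: base/base scores +-1, base/gap -2, gap/gap 0; a new gap
    column costs 2 per base it faces.
    """
    ids_a, mat_a = a
    ids_b, mat_b = b
    ca, cb = _profile_counts(mat_a), _profile_counts(mat_b)
    bases_a, bases_b = ca.sum(1), cb.sum(1)
    na, nb = mat_a.shape[0], mat_b.shape[0]
    gaps_a, gaps_b = na - bases_a, nb - bases_b

    matches = ca @ cb.T
    bb = np.outer(bases_a, bases_b)
    gap_pairs = np.outer(bases_a, gaps_b) + np.outer(gaps_a, bases_b)
    S = (2 * matches - bb - _GAP * gap_pairs).astype(np.int32)

    g_row = (_GAP * nb * bases_a).astype(np.int64)  # vertical step at row i
    g_col = (_GAP * na * bases_b).astype(np.int64)  # horizontal step at col j
    la, lb = len(bases_a), len(bases_b)

    H = np.empty((la + 1, lb + 1), dtype=np.int64)
    H[0, 0] = 0
    H[1:, 0] = -np.cumsum(g_row)
    H[0, 1:] = -np.cumsum(g_col)
    Gc = np.concatenate(([0], np.cumsum(g_col)))
    for i in range(1, la + 1):
        prev = H[i - 1]
        V = np.maximum(prev[:-1] + S[i - 1], prev[1:] - g_row[i - 1])
        run = np.maximum.accumulate(np.concatenate(([H[i, 0]], V + Gc[1:])))
        H[i, 1:] = np.maximum(V, run[:-1] - Gc[1:])

    # traceback (diag > up > left on ties)
    i, j = la, lb
    take_a: list[int] = []  # original column index or -1 for a gap column
    take_b: list[int] = []
    while i > 0 or j > 0:
        if i > 0 and j > 0 and H[i, j] == H[i - 1, j - 1] + S[i - 1, j - 1]:
            take_a.append(i - 1)
            take_b.append(j - 1)
            i, j = i - 1, j - 1
        elif i > 0 and H[i, j] == H[i - 1, j] - g_row[i - 1]:
            take_a.append(i - 1)
            take_b.append(-1)
            i -= 1
        else:
            take_a.append(-1)
            take_b.append(j - 1)
            j -= 1
    take_a.reverse()
    take_b.reverse()
    L = len(take_a)

    def expand(mat: np.ndarray, take: list[int]) -> np.ndarray:
        out = np.full((mat.shape[0], L), GAP, dtype=np.uint8)
        cols = np.array(take)
        keep = cols >= 0
        out[:, keep] = mat[:, cols[keep]]
        return out

    return ids_a + ids_b, np.vstack([expand(mat_a, take_a), expand(mat_b, take_b)])


def _align_builtin(seqs: list[Sequence]) -> Msa:
    order = sorted(range(len(seqs)), key=lambda i: seqs[i].id)
    seqs = [seqs[i] for i in order]
    profiles: list[tuple[list[str], np.ndarray]] = [
        ([s.id], encode(s.bases)[None, :]) for s in seqs
    ]
    if len(seqs) == 1:
        ids, mat = profiles[0]
        return Msa(ids, mat)
    if len(seqs) == 2:
        ids, mat = _merge_profiles(profiles[0], profiles[1])
        return Msa(ids, mat)
    Z = sch.linkage(_kmer_distance_condensed(seqs), method="average")
    nodes: dict[int, tuple[list[str], np.ndarray]] = dict(enumerate(profiles))
    n = len(seqs)
    for step, (left, right, _, _) in enumerate(Z):
        nodes[n + step] = _merge_profiles(nodes.pop(int(left)), nodes.pop(int(right)))
    ids, mat = nodes[n + len(Z) - 1]
    return Msa(ids, mat)


def _align_mafft(seqs: list[Sequence]) -> Msa:
    exe = shutil.which("mafft")
    if exe is None:
        raise BackendUnavailableError(
            "mafft not found on PATH; the builtin progressive aligner "
            "(backend='builtin') is available instead"
        )
    with tempfile.TemporaryDirectory() as tmp:
        fasta = Path(tmp) / "in.fasta"
        with open(fasta, "w") as fh:
            for s in seqs:
                fh.write(f">{s.id}\n{s.bases}\n")
        out = subprocess.run(
            [exe, "--auto", "--quiet", str(fasta)],
            capture_output=True,
            text=True,
            check=True,
        ).stdout
    ids: list[str] = []
    rows: list[str] = []
    for line in out.splitlines():
        if line.startswith(">"):
            ids.append(line[1:].strip())
            rows.append("")
        elif line.strip():
            rows[-1] += line.strip().upper()
    return Msa(ids, np.vstack([_encode_gapped(r) for r in rows]))


def align(seqs: list[Sequence], backend: str = "builtin") -> Msa:
    """Multiple sequence alignment; deterministic and input-order invariant."""
    if not seqs:
        raise ValueError("no sequences to align")
    if len({s.id for s in seqs}) != len(seqs):
        raise ValueError("sequence ids must be unique")
    if backend == "builtin":
        return _align_builtin(seqs)
    if backend == "mafft":
        return _align_mafft(seqs)
    raise ValueError(f"unknown aligner backend {backend!r}")


# ---------------------------------------------------------------------------
# Kimura two-parameter statistics


@dataclass
class PairStats:
    """K2P statistics for one pair of aligned rows.

    ``P`` and ``Q`` are the transition- and transversion-difference
    proportions over sites where both rows carry a base; the distance is
    ``d = -1/2 ln((1-2P-Q) sqrt(1-2Q))`` and the ts/tv ratio estimate is
    ``d_s/d_v`` with ``d_s = -1/2 ln(1-2P-Q) + 1/4 ln(1-2Q)`` and
    ``d_v = -1/2 ln(1-2Q)``.  ``defined`` is False when the logarithms are
    non-positive (saturated pair) or no sites are comparable.
    """

    P: float
    Q: float
    n_sites: int
    d: float
    d_s: float
    d_v: float
    r_pair: float
    defined: bool


def _k2p_from_counts(n_ts: float, n_tv: float, n_sites: float) -> PairStats:
    if n_sites <= 0:
        return PairStats(np.nan, np.nan, 0, np.nan, np.nan, np.nan, np.nan, False)
    P = n_ts / n_sites
    Q = n_tv / n_sites
    w1 = 1.0 - 2.0 * P - Q
    w2 = 1.0 - 2.0 * Q
    if w1 <= 0 or w2 <= 0:
        return PairStats(P, Q, int(n_sites), np.nan, np.nan, np.nan, np.nan, False)
    d = -0.5 * np.log(w1 * np.sqrt(w2))
    d_s = -0.5 * np.log(w1) + 0.25 * np.log(w2)
    d_v = -0.5 * np.log(w2)
    r = d_s / d_v if d_v > 0 else np.nan
    return PairStats(P, Q, int(n_sites), float(d), float(d_s), float(d_v), float(r), True)


def _pair_site_counts(a: np.ndarray, b: np.ndarray) -> tuple[int, int, int]:
    valid = (a != GAP) & (b != GAP)
    av, bv = a[valid], b[valid]
    diff = av != bv
    ts = diff & ((av ^ bv) == 2)
    return int(ts.sum()), int((diff & ~ts).sum()), int(valid.sum())


def pair_stats(row_a, row_b) -> PairStats:
    """K2P statistics for two equal-length gapped rows (strings or codes)."""
    a = _encode_gapped(row_a) if isinstance(row_a, str) else np.asarray(row_a)
    b = _encode_gapped(row_b) if isinstance(row_b, str) else np.asarray(row_b)
    if a.shape != b.shape:
        raise ValueError("rows must have equal length")
    return _k2p_from_counts(*_pair_site_counts(a, b))


@dataclass
class OverallStats:
    """Set-level distance statistics: mean pairwise K2P distance and the
    ts/tv ratio from site counts pooled over all pairs."""

    dbar: float
    r_k2i: float
    n_pairs: int
    n_excluded: int


def overall_stats(msa: Msa) -> OverallStats:
    if msa.n_rows < 2:
        raise ValueError("need at least two rows")
    dists = []
    n_excluded = 0
    ts_tot = tv_tot = sites_tot = 0
    for i, j in itertools.combinations(range(msa.n_rows), 2):
        ts, tv, n = _pair_site_counts(msa.matrix[i], msa.matrix[j])
        ts_tot += ts
        tv_tot += tv
        sites_tot += n
        ps = _k2p_from_counts(ts, tv, n)
        if ps.defined:
            dists.append(ps.d)
        else:
            n_excluded += 1
    if not dists:
        raise AttributeUndefinedError("all pairwise distances are undefined")
    pooled = _k2p_from_counts(ts_tot, tv_tot, sites_tot)
    return OverallStats(
        dbar=float(np.mean(dists)),
        r_k2i=pooled.r_pair,
        n_pairs=len(dists),
        n_excluded=n_excluded,
    )


def _pair_class_matrices(msa: Msa) -> np.ndarray:
    """Stacked per-pair site-class indicators, shape (3*P, L): transition
    differences, transversion differences, comparable sites."""
    pairs = list(itertools.combinations(range(msa.n_rows), 2))
    L = msa.n_cols
    ts = np.empty((len(pairs), L), dtype=np.int32)
    tv = np.empty_like(ts)
    val = np.empty_like(ts)
    for k, (i, j) in enumerate(pairs):
        a, b = msa.matrix[i], msa.matrix[j]
        v = (a != GAP) & (b != GAP)
        diff = v & (a != b)
        t = diff & ((a ^ b) == 2)
        ts[k], tv[k], val[k] = t, diff & ~t, v
    return np.vstack([ts, tv, val])


def sed_bootstrap(
    msa: Msa, reps: int = 500, rng: np.random.Generator | None = None
) -> float:
    """Bootstrap standard error of the mean pairwise distance.

    Resamples alignment columns with replacement ``reps`` times, recomputes
    the mean K2P distance for each replicate, and returns the sample
    standard deviation across replicates.
    """
    if reps < 2:
        raise ValueError("need at least 2 bootstrap replicates")
    if rng is None:
        rng = np.random.default_rng()
    L = msa.n_cols
    if L < 2:
        warnings.warn("degenerate single-column alignment; SE set to 0")
        return 0.0
    C = _pair_class_matrices(msa)
    n_pairs = C.shape[0] // 3
    W = np.empty((L, reps), dtype=np.int32)
    for r in range(reps):
        W[:, r] = np.bincount(rng.integers(0, L, L), minlength=L)
    counts = C @ W  # (3P, reps)
    ts = counts[:n_pairs].astype(float)
    tv = counts[n_pairs : 2 * n_pairs].astype(float)
    val = counts[2 * n_pairs :].astype(float)
    with np.errstate(divide="ignore", invalid="ignore"):
        P = ts / val
        Q = tv / val
        w1 = 1.0 - 2.0 * P - Q
        w2 = 1.0 - 2.0 * Q
        ok = (val > 0) & (w1 > 0) & (w2 > 0)
        d = np.where(ok, -0.5 * (np.log(np.where(ok, w1, 1.0)) + 0.5 * np.log(np.where(ok, w2, 1.0))), np.nan)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        dbar = np.nanmean(d, axis=0)
    dbar = dbar[np.isfinite(dbar)]
    if dbar.size < 2:
        return 0.0
    return float(np.std(dbar, ddof=1))


# ---------------------------------------------------------------------------
# tree inference and topology scoring


def k2p_distance_matrix(msa: Msa) -> tuple[np.ndarray, int]:
    """Symmetric K2P distance matrix; undefined (saturated) pairs are imputed
    as twice the largest defined distance.  Returns (matrix, n_imputed)."""
    n = msa.n_rows
    dm = np.zeros((n, n))
    undef: list[tuple[int, int]] = []
    for i, j in itertools.combinations(range(n), 2):
        ps = pair_stats(msa.matrix[i], msa.matrix[j])
        if ps.defined:
            dm[i, j] = dm[j, i] = ps.d
        else:
            undef.append((i, j))
    fill = 2.0 * dm.max() if dm.max() > 0 else 1.0
    for i, j in undef:
        dm[i, j] = dm[j, i] = fill
    return dm, len(undef)


def nj_tree(dm: np.ndarray, ids: list[str], outgroup: str | None = None) -> GuideTree:
    """Neighbor joining on a distance matrix, displayed rooted at the
    internal node adjacent to the outgroup leaf (default: lexicographically
    smallest label), with negative branch lengths clamped to zero."""
    if len(ids) < 4:
        raise StructureError("tree inference needs at least 4 sequences")
    sk = skbio.tree.nj(DistanceMatrix(dm, ids=ids))

    # undirected adjacency with degree-2 nodes suppressed
    adj: dict[int, list[tuple[int, float]]] = {}
    names: dict[int, str] = {}
    counter = itertools.count()
    node_id: dict[int, int] = {}

    def nid(node) -> int:
        key = id(node)
        if key not in node_id:
            node_id[key] = next(counter)
            names[node_id[key]] = node.name or ""
        return node_id[key]

    for node in sk.traverse():
        u = nid(node)
        adj.setdefault(u, [])
        for child in node.children:
            v = nid(child)
            w = max(0.0, float(child.length or 0.0))
            adj[u].append((v, w))
            adj.setdefault(v, []).append((u, w))

    changed = True
    while changed:
        changed = False
        for u in list(adj):
            if len(adj[u]) == 2 and not names[u]:
                (a, wa), (b, wb) = adj[u]
                adj[a] = [(x, w) for x, w in adj[a] if x != u] + [(b, wa + wb)]
                adj[b] = [(x, w) for x, w in adj[b] if x != u] + [(a, wa + wb)]
                del adj[u]
                changed = True

    leaf_ids = {u for u in adj if len(adj[u]) == 1}
    out_label = outgroup if outgroup is not None else min(ids)
    try:
        out_id = next(u for u in leaf_ids if names[u] == out_label)
    except StopIteration:
        raise LookupError(f"outgroup leaf {out_label!r} not in tree") from None
    root_id = adj[out_id][0][0]

    as_counter = itertools.count(1)

    def build(u: int, parent: int | None, length: float | None) -> TreeNode:
        neighbours = [(v, w) for v, w in adj[u] if v != parent]
        if not neighbours:
            return TreeNode(names[u], length)
        label = f"AS_{next(as_counter)}"
        children = [build(v, u, w) for v, w in neighbours]
        return TreeNode(label, length, children)

    return GuideTree(build(root_id, None, None))


def infer_tree(
    data: Msa | list[Sequence],
    outgroup: str | None = None,
    backend: str = "builtin",
) -> GuideTree:
    """NJ tree of a sequence set (aligning first when given raw sequences),
    using the K2P distance matrix with saturated pairs imputed."""
    msa = data if isinstance(data, Msa) else align(data, backend=backend)
    dm, _ = k2p_distance_matrix(msa)
    return nj_tree(dm, msa.ids, outgroup=outgroup)


class BranchForm(enum.Enum):
    """Leaf branch geometry in the ladderized drawing."""

    L_SHAPE = "L"
    INV_L_SHAPE = "inverted-L"
    STRAIGHT = "straight"


def branch_form(layout: LadderLayout, leaf: str) -> BranchForm:
    """Classify a leaf branch: inverted-L when the leaf sits strictly above
    its parent's row, L when strictly below, straight within half a row."""
    if leaf not in layout.leaf_row:
        raise LookupError(f"unknown leaf {leaf!r}")
    diff = layout.leaf_row[leaf] - layout.leaf_parent_row[leaf]
    if abs(diff) < 0.5:
        return BranchForm.STRAIGHT
    return BranchForm.L_SHAPE if diff > 0 else BranchForm.INV_L_SHAPE


def relative_location(layout: LadderLayout, leaf: str) -> str:
    """Label of the leaf in the row immediately above, or :data:`TOP`."""
    if leaf not in layout.leaf_row:
        raise LookupError(f"unknown leaf {leaf!r}")
    row = layout.leaf_row[leaf]
    return TOP if row == 0 else layout.leaf_order[row - 1]


def topology_score(
    test_tree: GuideTree,
    ref_tree: GuideTree,
    match: dict[str, str] | None = None,
) -> int:
    """Per-leaf concordance of branch form and relative location.

    ``match`` maps test-tree leaves to their reference correspondents
    (identity by default).  Each leaf contributes one point if its branch
    form agrees and one point if the leaf above it (mapped through
    ``match``; :data:`TOP` matches only :data:`TOP`) agrees, so the score
    lies in ``[0, 2N]`` and a tree scored against itself yields ``2N``.
    """
    test_layout = ladderize(test_tree)
    ref_layout = ladderize(ref_tree)
    test_leaves = set(test_layout.leaf_order)
    ref_leaves = set(ref_layout.leaf_order)
    if match is None:
        match = {lab: lab for lab in test_leaves}
    if (
        set(match) != test_leaves
        or set(match.values()) != ref_leaves
        or len(set(match.values())) != len(match)
    ):
        raise ValueError("match must be a bijection between test and reference leaves")
    score = 0
    for leaf in test_layout.leaf_order:
        ref_leaf = match[leaf]
        if branch_form(test_layout, leaf) == branch_form(ref_layout, ref_leaf):
            score += 1
        above = relative_location(test_layout, leaf)
        mapped = TOP if above == TOP else match[above]
        if mapped == relative_location(ref_layout, ref_leaf):
            score += 1
    return score


# ---------------------------------------------------------------------------
# composition


@dataclass
class AttributeConfig:
    """Knobs of the attribute pipeline."""

    backend: str = "builtin"
    bootstrap_reps: int = 500
    seed: int = 0
    outgroup: str | None = None
    invariant_correction: bool = False


@dataclass
class AttributeSet:
    """The five attributes of one sequence set."""

    L_MSA: int
    R_K2I: float
    Dbar: float
    SEDbar: float
    TS_ML: int

    def as_dict(self) -> dict:
        return {
            "L_MSA": self.L_MSA,
            "R_K2I": self.R_K2I,
            "Dbar": self.Dbar,
            "SEDbar": self.SEDbar,
            "TS_ML": self.TS_ML,
        }


def _drop_invariant_columns(msa: Msa) -> Msa:
    """Crude invariant-sites correction: remove columns where every row
    carries the same base (no gaps)."""
    m = msa.matrix
    constant = (m == m[0]).all(axis=0) & (m[0] != GAP)
    if constant.all():
        return msa
    return Msa(msa.ids, m[:, ~constant])


def attribute_set(
    seqs: list[Sequence],
    ref_tree: GuideTree,
    config: AttributeConfig | None = None,
) -> AttributeSet:
    """Full pipeline: align, distance statistics, bootstrap SE, NJ tree,
    topology score against ``ref_tree`` (leaves matched by label)."""
    config = config or AttributeConfig()
    msa = align(seqs, backend=config.backend)
    L_MSA = msa.n_cols
    stats_msa = _drop_invariant_columns(msa) if config.invariant_correction else msa
    ov = overall_stats(stats_msa)
    sed = sed_bootstrap(
        stats_msa, reps=config.bootstrap_reps, rng=np.random.default_rng(config.seed)
    )
    tree = infer_tree(msa, outgroup=config.outgroup)
    ts = topology_score(tree, ref_tree)
    return AttributeSet(L_MSA, ov.r_k2i, ov.dbar, sed, ts)
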
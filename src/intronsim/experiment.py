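"""Experiment orchestration: orthogonal screening, named optimization runs,
and the one-base-perturbation reference distribution.

The parameter screen uses the standard L16(4^5) orthogonal array: sixteen
runs accommodate five factors at four levels with every level appearing
four times per factor and every ordered level pair appearing exactly once
for every factor pair.  The factor levels are the published design for the
two models (deletion and insertion variants share the per-event ranges).

The reference distribution emulates how the real intron set is summarised:
each reference sequence receives exactly one substitution per replicate,
the five attributes are recomputed, and their mean and standard deviation
over replicates define the comparison target.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .attributes import AttributeConfig, attribute_set, align, infer_tree
from .core import Sequence, SubstitutionSampler, mutate
from .engine import MD, MI, ModelParams, run
from .tree import GuideTree, fixture_tree

__all__ = [
    "FACTORS",
    "FACTOR_TABLE",
    "OrthogonalDesign",
    "ReferenceDistribution",
    "l16_design",
    "materialize_tests",
    "run_orthogonal",
    "named_tests",
    "perturb_reference",
    "synthetic_reference",
    "derive_seed",
]

FACTORS = ("L_AS1", "L_AS12", "M_1", "L_ID", "M_ID")

_ID_RANGES = ((31, 50), (71, 90), (111, 130), (151, 170))
_MUT_RANGES = ((11, 20), (21, 30), (31, 40), (41, 50))

#: Factor levels of the orthogonal design, per model.
FACTOR_TABLE: dict[str, dict[str, tuple]] = {
    MD: {
        "L_AS1": (4000, 5000, 6000, 7000),
        "L_AS12": (2000, 2250, 2500, 2750),
        "M_1": (200, 400, 600, 800),
        "L_ID": _ID_RANGES,
        "M_ID": _MUT_RANGES,
    },
    MI: {
        "L_AS1": (10, 20, 30, 40),
        "L_AS12": (110, 120, 130, 140),
        "M_1": (200, 400, 600, 800),
        "L_ID": _ID_RANGES,
        "M_ID": _MUT_RANGES,
    },
}

# GF(4) multiplication table over elements {0,1,2,3} = {0, 1, x, x+1},
# x^2 = x + 1; addition is bitwise XOR.
_GF4_MUL = (
    (0, 0, 0, 0),
    (0, 1, 2, 3),
    (0, 2, 3, 1),
    (0, 3, 1, 2),
)


@dataclass
class OrthogonalDesign:
    """An orthogonal array of levels 1..4, one row per test."""

    matrix: np.ndarray
    factor_names: tuple[str, ...] = FACTORS

    @property
    def n_tests(self) -> int:
        return self.matrix.shape[0]


def l16_design() -> OrthogonalDesign:
    """The standard L16(4^5) array built from two GF(4) digits.

    Row ``r`` has digits ``a = r // 4`` and ``b = r % 4``; the five columns
    are ``a``, ``b``, ``a+b``, ``a+2b``, ``a+3b`` in GF(4), shifted to
    levels 1..4.  Any two columns are linearly independent combinations of
    ``(a, b)``, which yields exact pairwise balance.
    """
    rows = []
    for r in range(16):
        a, b = divmod(r, 4)
        cols = (
            a,
            b,
            a ^ b,
            a ^ _GF4_MUL[2][b],
            a ^ _GF4_MUL[3][b],
        )
        rows.append([c + 1 for c in cols])
    return OrthogonalDesign(np.array(rows, dtype=int))


def derive_seed(master_seed: int, *parts) -> int:
    """Stable per-run seed below 2^31 derived from a master seed and tags."""
    tag = "|".join(str(p) for p in parts).encode()
    return zlib.crc32(tag, master_seed & 0xFFFFFFFF) & 0x7FFFFFFF


def materialize_tests(
    design: OrthogonalDesign,
    mode: str,
    factor_table: dict | None = None,
    master_seed: int = 0,
    R: float = 1.5,
) -> list[tuple[str, ModelParams]]:
    """Instantiate every design row as a fully specified parameter set."""
    table = (factor_table or FACTOR_TABLE)[mode]
    missing = [f for f in design.factor_names if f not in table]
    if missing:
        raise KeyError(f"factor table lacks {missing}")
    out = []
    for i, row in enumerate(design.matrix):
        levels = dict(zip(design.factor_names, row))
        test_id = f"{mode}_{i + 1}"
        params = ModelParams(
            mode=mode,
            L_AS1=table["L_AS1"][levels["L_AS1"] - 1],
            L_AS12=table["L_AS12"][levels["L_AS12"] - 1],
            M_1=table["M_1"][levels["M_1"] - 1],
            L_ID=table["L_ID"][levels["L_ID"] - 1],
            M_ID=table["M_ID"][levels["M_ID"] - 1],
            R=R,
            seed=derive_seed(master_seed, test_id),
        )
        out.append((test_id, params))
    return out


_RESULT_COLUMNS = [
    "test_id",
    "replicate",
    "seed",
    "L_AS1",
    "L_AS12",
    "M_1",
    "L_ID",
    "M_ID",
    "L_MSA",
    "R_K2I",
    "Dbar",
    "SEDbar",
    "TS_ML",
    "error",
]


def _result_row(test_id: str, rep: int, seed: int, params: ModelParams) -> dict:
    return {
        "test_id": test_id,
        "replicate": rep,
        "seed": seed,
        "L_AS1": params.L_AS1,
        "L_AS12": params.L_AS12,
        "M_1": params.M_1,
        "L_ID": f"{params.L_ID[0]}-{params.L_ID[1]}",
        "M_ID": f"{params.M_ID[0]}-{params.M_ID[1]}",
        "L_MSA": np.nan,
        "R_K2I": np.nan,
        "Dbar": np.nan,
        "SEDbar": np.nan,
        "TS_ML": np.nan,
        "error": "",
    }


def _run_tests(
    tests: list[tuple[str, ModelParams]],
    tree: GuideTree,
    reps: int,
    master_seed: int,
    config: AttributeConfig | None,
) -> pd.DataFrame:
    config = config or AttributeConfig()
    rows = []
    for test_id, base in tests:
        for rep in range(reps):
            seed = derive_seed(master_seed, test_id, rep)
            params = base.with_seed(seed)
            row = _result_row(test_id, rep, seed, params)
            try:
                result = run(tree, params)
                aset = attribute_set(
                    list(result.leaves.values()),
                    ref_tree=tree,
                    config=replace(config, seed=derive_seed(seed, "boot")),
                )
                row.update(aset.as_dict())
            except Exception as exc:  # per-run isolation
                row["error"] = f"{type(exc).__name__}: {exc}"
            rows.append(row)
    return pd.DataFrame(rows, columns=_RESULT_COLUMNS)


def run_orthogonal(
    mode: str,
    tree: GuideTree,
    reps: int = 10,
    master_seed: int = 0,
    config: AttributeConfig | None = None,
) -> pd.DataFrame:
    """Run the full orthogonal screen: 16 tests x ``reps`` replicates.

    Every replicate simulates one 14-sequence set and determines its five
    attributes against the guide tree; the result is a tidy table fully
    reproducible from ``master_seed``.
    """
    tests = materialize_tests(l16_design(), mode, master_seed=master_seed)
    return _run_tests(tests, tree, reps, master_seed, config)


#: Parameter sets of the named optimization runs (scalar factors followed by
#: the per-event indel and mutation ranges).
_NAMED: dict[str, tuple] = {
    "MD_17": (6000, 2000, 600, (31, 50), (21, 30)),
    "MD_18": (6000, 2500, 800, (31, 50), (21, 30)),
    "MD_19": (6000, 2000, 800, (31, 50), (41, 50)),
    "MD_20": (5000, 2500, 800, (31, 50), (21, 30)),
    "MD_21": (6000, 2250, 800, (31, 50), (11, 20)),
    "MD_22": (6000, 2250, 800, (31, 50), (41, 50)),
    "MD_23": (6000, 2000, 800, (31, 50), (21, 30)),
    "MD_24": (6000, 2500, 800, (31, 50), (11, 20)),
    "MI_17": (10, 120, 200, (31, 50), (31, 40)),
    "MI_18": (10, 120, 200, (31, 50), (11, 20)),
    "MI_19": (10, 120, 800, (31, 50), (11, 20)),
    "MI_20": (20, 120, 200, (31, 50), (11, 20)),
    "MI_21": (10, 110, 800, (31, 50), (11, 20)),
    "MI_22": (40, 110, 200, (31, 50), (11, 20)),
    "MI_23": (20, 120, 200, (151, 170), (11, 20)),
    "MI_24": (10, 120, 800, (151, 170), (11, 20)),
}


def named_tests(mode: str, R: float = 1.5) -> dict[str, ModelParams]:
    """The eight named optimization parameter sets for one model."""
    if mode not in (MD, MI):
        raise LookupError(f"unknown mode {mode!r}")
    out = {}
    for test_id, (l1, l12, m1, lid, mid) in _NAMED.items():
        if test_id.startswith(mode):
            out[test_id] = ModelParams(
                mode=mode, L_AS1=l1, L_AS12=l12, M_1=m1, L_ID=lid, M_ID=mid, R=R
            )
    return out


def run_named(
    mode: str,
    tree: GuideTree,
    reps: int = 10,
    master_seed: int = 0,
    config: AttributeConfig | None = None,
) -> pd.DataFrame:
    """Run the named optimization tests, same result schema as the screen."""
    tests = [
        (tid, p.with_seed(derive_seed(master_seed, tid)))
        for tid, p in sorted(named_tests(mode).items())
    ]
    return _run_tests(tests, tree, reps, master_seed, config)


@dataclass
class ReferenceDistribution:
    """Mean and SD of each attribute over perturbation replicates."""

    means: dict[str, float]
    sds: dict[str, float]
    n_reps: int
    records: pd.DataFrame = field(repr=False, default=None)

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"mean": self.means, "sd": self.sds}
        ).rename_axis("attribute")


def perturb_reference(
    ref_seqs: list[Sequence],
    ref_tree: GuideTree,
    reps: int = 10,
    rng: np.random.Generator | None = None,
    config: AttributeConfig | None = None,
    n_mutations: int = 1,
    R: float = 1.5,
) -> ReferenceDistribution:
    """Attribute distribution of the reference set under minimal perturbation.

    Per replicate every sequence receives exactly ``n_mutations``
    substitutions at uniform internal positions (no length change), and the
    five attributes are recomputed against ``ref_tree``.
    """
    if rng is None:
        rng = np.random.default_rng()
    config = config or AttributeConfig()
    labels = set(ref_tree.leaf_labels)
    if {s.id for s in ref_seqs} != labels:
        raise ValueError("reference sequence ids must match the tree leaves")
    records = []
    for rep in range(reps):
        sampler = SubstitutionSampler(R, rng)
        perturbed = [
            mutate(s, n_mutations, sampler, protect_termini=True)[0]
            for s in ref_seqs
        ]
        # one shared column-resampling seed: replicate variance then reflects
        # the perturbations alone, and an unperturbed control has zero SD
        aset = attribute_set(
            perturbed,
            ref_tree,
            config=replace(config, seed=derive_seed(config.seed, "perturb")),
        )
        records.append({"replicate": rep, **aset.as_dict()})
    frame = pd.DataFrame(records)
    attrs = ["L_MSA", "R_K2I", "Dbar", "SEDbar", "TS_ML"]
    means = {a: float(frame[a].mean()) for a in attrs}
    sds = {a: float(frame[a].std(ddof=1)) if reps > 1 else 0.0 for a in attrs}
    return ReferenceDistribution(means, sds, reps, frame)


def synthetic_reference(
    seed: int = 0,
    tree: GuideTree | None = None,
    config: AttributeConfig | None = None,
) -> tuple[list[Sequence], GuideTree]:
    """A synthetic stand-in for the real reference intron set.

    Generates one deletion-model run (the best-performing named parameter
    set) on the fixture guide tree and returns its 14 leaf sequences
    together with the tree inferred from them, which plays the role of the
    reference tree the real study reads off its sequence set.
    """
    config = config or AttributeConfig()
    if tree is None:
        tree = fixture_tree(seed)
    params = named_tests(MD)["MD_23"].with_seed(derive_seed(seed, "reference"))
    result = run(tree, params)
    seqs = list(result.leaves.values())
    ref_tree = infer_tree(align(seqs, backend=config.backend), outgroup=config.outgroup)
    return seqs, ref_tree
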
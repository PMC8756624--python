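"""Synthetic stroke-discharge cohorts with fixed per-outcome-group marginals.

The cohort emulated here is a set of 1468 patients hospitalised for
spontaneous supratentorial intracerebral hemorrhage, described by eight
categorical clinical variables and a binary discharge outcome
(``discharge_failure``: 1 = discharge failure, 0 = success).  Only the
per-outcome-group marginal distribution of each variable is publicly known,
so the generator reproduces those marginals exactly (``exact`` mode,
variables independent given the outcome) or samples from them
(``stochastic`` mode), optionally tilted by pairwise log-odds couplings so
that predictors carry information about the imputation target.

The imputation target throughout the package is ``volume_ge30ml``, the
supratentorial hemorrhage volume dichotomised at 30 ml.
"""

from __future__ import annotations

import dataclasses
from collections.abc import Mapping, Sequence
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "VariableSpec",
    "GroupProfile",
    "Cohort",
    "FeatureMatrix",
    "TARGET",
    "OUTCOME",
    "PREDICTORS",
    "table2_profile",
    "generate_cohort",
    "encode_features",
    "write_cohort",
    "read_cohort",
]

#: name of the binary outcome column (1 = discharge failure)
OUTCOME = "discharge_failure"

#: the amputation/imputation target variable
TARGET = "volume_ge30ml"


@dataclasses.dataclass(frozen=True)
class VariableSpec:
    """One categorical clinical variable and its per-group counts.

    ``categories`` is the canonical ordered list of category labels;
    ``success_counts`` / ``failure_counts`` are the number of patients in
    each category within the discharge-success and discharge-failure groups.
    """

    name: str
    categories: tuple[str, ...]
    success_counts: tuple[int, ...]
    failure_counts: tuple[int, ...]

    def proportions(self, group: str) -> np.ndarray:
        counts = np.asarray(self.counts(group), dtype=float)
        return counts / counts.sum()

    def counts(self, group: str) -> tuple[int, ...]:
        if group == "success":
            return self.success_counts
        if group == "failure":
            return self.failure_counts
        raise ValueError(f"unknown group {group!r}")


@dataclasses.dataclass(frozen=True)
class GroupProfile:
    """Per-outcome-group categorical count tables defining a cohort."""

    n_success: int
    n_failure: int
    variables: tuple[VariableSpec, ...]

    def __post_init__(self) -> None:
        for var in self.variables:
            if len(var.categories) != len(var.success_counts) or len(
                var.categories
            ) != len(var.failure_counts):
                raise ValueError(f"{var.name}: category/count length mismatch")
            if sum(var.success_counts) != self.n_success:
                raise ValueError(
                    f"{var.name}: success counts sum to "
                    f"{sum(var.success_counts)}, expected {self.n_success}"
                )
            if sum(var.failure_counts) != self.n_failure:
                raise ValueError(
                    f"{var.name}: failure counts sum to "
                    f"{sum(var.failure_counts)}, expected {self.n_failure}"
                )

    @property
    def n_total(self) -> int:
        return self.n_success + self.n_failure

    def variable(self, name: str) -> VariableSpec:
        for var in self.variables:
            if var.name == name:
                return var
        raise KeyError(name)

    @property
    def variable_names(self) -> tuple[str, ...]:
        return tuple(v.name for v in self.variables)


@dataclasses.dataclass
class Cohort:
    """A complete cohort: one row per patient, categories as strings."""

    records: pd.DataFrame
    provenance: dict

    @property
    def n(self) -> int:
        return len(self.records)


@dataclasses.dataclass
class FeatureMatrix:
    """Numeric design matrix with invertible column metadata.

    ``columns`` maps each matrix column to ``(source_variable, label)``
    where *label* is the category for one-hot columns or ``"code"`` for
    ordinal/binary codes.  The target variable is always encoded as a single
    0/1 column so encoding is invertible for it.
    """

    matrix: np.ndarray
    columns: list[tuple[str, str]]
    category_maps: dict[str, tuple[str, ...]]
    scheme: str

    def column_index(self, variable: str) -> list[int]:
        return [i for i, (src, _) in enumerate(self.columns) if src == variable]

    def decode_target(self, codes: np.ndarray) -> np.ndarray:
        cats = self.category_maps[TARGET]
        codes = np.asarray(codes).astype(int)
        return np.asarray(cats, dtype=object)[codes]


# Per-group category counts of the reference cohort (success n=1207,
# failure n=261): age band, gender, more-than-two prior hospitalisations,
# deep coma at admission, diagnostic location, hemorrhage volume >=30 ml,
# surgical operation, co-infection.
_PROFILE_SPEC: list[tuple[str, list[str], list[int], list[int]]] = [
    ("age", ["<55", "55-64", "65-74", "75-84", ">84"],
     [249, 265, 391, 246, 56], [37, 51, 86, 60, 27]),
    ("gender", ["male", "female"], [688, 519], [163, 98]),
    ("readmission_gt2", ["no", "yes"], [1194, 13], [251, 10]),
    ("deep_coma", ["no", "yes"], [1190, 17], [130, 131]),
    ("location", ["deep", "superficial"], [1081, 126], [220, 41]),
    (TARGET, ["<30 ml", ">=30 ml"], [1032, 175], [128, 133]),
    ("operation", ["no", "yes"], [1045, 162], [203, 58]),
    ("co_infection", ["no", "yes"], [802, 405], [138, 123]),
]

#: the eight clinical variables, in canonical order
PREDICTORS = tuple(name for name, *_ in _PROFILE_SPEC)

#: canonical CSV column order
CSV_COLUMNS = PREDICTORS + (OUTCOME,)

#: default within-group log-odds couplings for stochastic generation:
#: larger hemorrhage volume co-occurs with deep coma, surgery and
#: co-infection, giving imputers a within-group signal to exploit
DEFAULT_DEPENDENCE: dict[tuple[str, str], float] = {
    ("deep_coma", TARGET): 2.5,
    ("operation", TARGET): 1.5,
    ("co_infection", TARGET): 1.0,
}


def table2_profile() -> GroupProfile:
    """Return the canonical cohort profile (1207 successes, 261 failures)."""
    variables = tuple(
        VariableSpec(name, tuple(cats), tuple(s), tuple(f))
        for name, cats, s, f in _PROFILE_SPEC
    )
    return GroupProfile(n_success=1207, n_failure=261, variables=variables)


def _category_score(var: VariableSpec, index: int) -> float:
    # normalised ordinal score in [0, 1]; for binary variables this is the
    # plain indicator of the second-listed ("yes"-like) category
    k = len(var.categories)
    return 0.0 if k == 1 else index / (k - 1)


def _generate_group_exact(
    profile: GroupProfile, group: str, rng: np.random.Generator
) -> pd.DataFrame:
    n = profile.n_success if group == "success" else profile.n_failure
    data = {}
    for var in profile.variables:
        values = np.repeat(
            np.asarray(var.categories, dtype=object), var.counts(group)
        )
        data[var.name] = rng.permutation(values)
    df = pd.DataFrame(data)
    df[OUTCOME] = 0 if group == "success" else 1
    return df


def _generate_group_stochastic(
    profile: GroupProfile,
    group: str,
    n: int,
    dependence: Mapping[tuple[str, str], float] | None,
    rng: np.random.Generator,
) -> pd.DataFrame:
    # autoregressive sampling in canonical variable order: each variable's
    # category logits are the log marginal proportions plus coupling terms
    # lambda * s(u) * s(v) against already-sampled variables
    dependence = dict(dependence or {})
    couplings: dict[str, list[tuple[str, float]]] = {}
    order = list(profile.variable_names)
    for (u, v), lam in dependence.items():
        if u not in order or v not in order:
            raise ValueError(f"unknown variable in coupling ({u}, {v})")
        if not np.isfinite(lam):
            raise ValueError("coupling strengths must be finite")
        first, second = (u, v) if order.index(u) < order.index(v) else (v, u)
        couplings.setdefault(second, []).append((first, lam))

    columns: dict[str, np.ndarray] = {}
    scores: dict[str, np.ndarray] = {}
    for var in profile.variables:
        logits = np.tile(
            np.log(var.proportions(group) + 1e-12), (n, 1)
        )
        for other, lam in couplings.get(var.name, []):
            cat_scores = np.array(
                [_category_score(var, i) for i in range(len(var.categories))]
            )
            logits += lam * np.outer(scores[other], cat_scores)
        probs = np.exp(logits - logits.max(axis=1, keepdims=True))
        probs /= probs.sum(axis=1, keepdims=True)
        # inverse-CDF draw per record
        u = rng.random(n)
        idx = (probs.cumsum(axis=1) < u[:, None]).sum(axis=1)
        columns[var.name] = np.asarray(var.categories, dtype=object)[idx]
        scores[var.name] = np.array(
            [_category_score(var, i) for i in idx]
        )
    df = pd.DataFrame(columns)
    df[OUTCOME] = 0 if group == "success" else 1
    return df


def generate_cohort(
    profile: GroupProfile,
    mode: str = "exact",
    dependence: Mapping[tuple[str, str], float] | None = None,
    seed: int = 0,
    group_sizes: tuple[int, int] | None = None,
) -> Cohort:
    """Generate a complete cohort from a group profile.

    Parameters
    ----------
    profile:
        Per-group categorical count tables.
    mode:
        ``"exact"`` reproduces every per-group marginal count exactly
        (values assigned by seeded permutation, variables independent given
        the outcome).  ``"stochastic"`` samples categories per group from
        the profile proportions, optionally tilted by ``dependence``.
    dependence:
        Mapping ``(var_u, var_v) -> log-odds coupling strength`` applied in
        stochastic mode; positive values make high categories of the two
        variables co-occur within a group.
    seed:
        Seed for the permutation / sampling RNG.
    group_sizes:
        Optional ``(n_success, n_failure)`` override, stochastic mode only.
    """
    rng = np.random.default_rng(seed)
    if mode == "exact":
        if group_sizes is not None:
            raise ValueError("group_sizes only applies to stochastic mode")
        parts = [
            _generate_group_exact(profile, "success", rng),
            _generate_group_exact(profile, "failure", rng),
        ]
    elif mode == "stochastic":
        n_s, n_f = group_sizes or (profile.n_success, profile.n_failure)
        parts = [
            _generate_group_stochastic(profile, "success", n_s, dependence, rng),
            _generate_group_stochastic(profile, "failure", n_f, dependence, rng),
        ]
    else:
        raise ValueError(f"unknown mode {mode!r}")

    records = pd.concat(parts, ignore_index=True)
    # seeded shuffle so the outcome groups are interleaved
    records = records.iloc[rng.permutation(len(records))].reset_index(drop=True)
    records = records[list(CSV_COLUMNS)]
    return Cohort(
        records=records,
        provenance={"mode": mode, "seed": seed, "dependence": dependence or {}},
    )


def encode_features(
    records: pd.DataFrame,
    scheme: str = "onehot",
    profile: GroupProfile | None = None,
    include: Sequence[str] | None = None,
) -> FeatureMatrix:
    """Encode a cohort frame into a numeric design matrix.

    ``"onehot"``: binary variables become single 0/1 columns; variables with
    more than two categories (age) expand to one indicator column per
    category.  ``"tree"``: every variable becomes ordinal integer codes
    (age 0-4), the convention for tree ensembles.  The outcome column, when
    included, is passed through as 0/1.
    """
    if scheme not in ("onehot", "tree"):
        raise ValueError(f"unknown encoding scheme {scheme!r}")
    profile = profile or table2_profile()
    include = list(include) if include is not None else list(records.columns)

    cols: list[np.ndarray] = []
    meta: list[tuple[str, str]] = []
    category_maps: dict[str, tuple[str, ...]] = {}
    for name in include:
        if name == OUTCOME:
            cols.append(records[OUTCOME].to_numpy(dtype=float))
            meta.append((OUTCOME, "code"))
            category_maps[OUTCOME] = ("0", "1")
            continue
        var = profile.variable(name)
        category_maps[name] = var.categories
        codes = pd.Categorical(
            records[name], categories=list(var.categories)
        ).codes
        if (codes < 0).any():
            bad = set(records[name]) - set(var.categories)
            raise ValueError(f"unseen category in {name}: {sorted(bad)}")
        if scheme == "tree" or len(var.categories) == 2:
            cols.append(codes.astype(float))
            meta.append((name, "code"))
        else:
            for j, cat in enumerate(var.categories):
                cols.append((codes == j).astype(float))
                meta.append((name, cat))
    matrix = np.column_stack(cols) if cols else np.empty((len(records), 0))
    return FeatureMatrix(matrix, meta, category_maps, scheme)


def write_cohort(cohort: Cohort | pd.DataFrame, path: str | Path) -> None:
    """Write a (possibly incomplete) cohort as CSV; missing cells are empty."""
    records = cohort.records if isinstance(cohort, Cohort) else cohort
    records[list(CSV_COLUMNS)].to_csv(path, index=False, na_rep="")


def read_cohort(path: str | Path, profile: GroupProfile | None = None) -> pd.DataFrame:
    """Read a cohort CSV; empty cells become pandas ``NA``.

    Category labels are validated against the profile; unknown labels raise.
    """
    profile = profile or table2_profile()
    df = pd.read_csv(
        path, dtype=str, keep_default_na=False, na_values=[""]
    )
    missing_cols = set(CSV_COLUMNS) - set(df.columns)
    if missing_cols:
        raise ValueError(f"malformed cohort file, missing columns {sorted(missing_cols)}")
    df[OUTCOME] = df[OUTCOME].astype(int)
    for var in profile.variables:
        observed = df[var.name].dropna()
        bad = set(observed) - set(var.categories)
        if bad:
            raise ValueError(f"unknown category in {var.name}: {sorted(bad)}")
    return df[list(CSV_COLUMNS)]
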
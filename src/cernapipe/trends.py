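"""Short time-series trend-profile clustering with permutation significance.

Genes measured over T ordered stages are reduced to a trend vector
(0, log2(v1/v0), ..., log2(v_{T-1}/v0)) and assigned to the closest of m
model profiles -- integer-valued trajectories starting at 0 whose
successive steps change by at most c units.  With the defaults T=4, c=1
there are 3^3 = 27 candidate trajectories, from which m=26 are kept by a
greedy max-min-distance selection seeded with the flat profile.

Assignment maximizes Pearson correlation between the 0-prefixed trend
vector and each (0-prefixed) model profile; all-zero vectors go to the
flat profile by convention.  Profile significance is a permutation test:
each gene's stage order is shuffled B times, genes are reassigned, and a
profile is enriched when its observed member count is rarely reached
(p_perm * m < alpha, Bonferroni over the m profiles).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._util import spawn_rng


@dataclass(frozen=True)
class TrendConfig:
    T: int = 4                  # number of stages
    c: int = 1                  # max unit change per step
    m: int = 26                 # number of model profiles kept
    n_permutations: int = 1000
    alpha: float = 0.05
    seed: int = 0
    pseudocount: float = 1.0

    def __post_init__(self):
        if self.T < 2:
            raise ValueError("T must be >= 2")
        if self.m > (2 * self.c + 1) ** (self.T - 1):
            raise ValueError("m exceeds the number of enumerable profiles")


@dataclass
class TrendVector:
    gene_id: str
    values: np.ndarray  # length T-1; conceptually prefixed by 0


@dataclass
class ProfileResult:
    profile_id: int
    model: tuple[int, ...]      # length T, starts at 0
    assigned: list[str] = field(default_factory=list)
    observed: int = 0
    expected: float = 0.0
    p_perm: float = 1.0
    significant: bool = False


def enumerate_candidates(T: int, c: int) -> list[tuple[int, ...]]:
    """All integer profiles of length T starting at 0 with steps in [-c, c],
    in lexicographic order of the step tuples."""
    out = []
    for steps in itertools.product(range(-c, c + 1), repeat=T - 1):
        prof = [0]
        for s in steps:
            prof.append(prof[-1] + s)
        out.append(tuple(prof))
    return out


def generate_model_profiles(config: TrendConfig) -> list[ProfileResult]:
    """Greedy max-min selection of m model profiles, seeded with flat.

    At each step the candidate with the largest minimum Euclidean
    distance to the already-selected set is added; ties break toward the
    earlier candidate in enumeration order.  Deterministic.
    """
    candidates = enumerate_candidates(config.T, config.c)
    flat = tuple([0] * config.T)
    cand = np.array(candidates, dtype=float)
    selected = [candidates.index(flat)]
    mind = np.linalg.norm(cand - cand[selected[0]], axis=1)
    while len(selected) < config.m:
        mind[selected] = -1.0
        best = int(np.argmax(mind))  # argmax takes the first max: lexicographic tie-break
        selected.append(best)
        mind = np.minimum(mind, np.linalg.norm(cand - cand[best], axis=1))
    return [ProfileResult(profile_id=i, model=candidates[j])
            for i, j in enumerate(selected)]


def transform_series(stage_means: np.ndarray, pseudocount: float = 1.0) -> np.ndarray:
    """(v0..v_{T-1}) -> (log2((v1+pc)/(v0+pc)), ..., log2((v_{T-1}+pc)/(v0+pc)))."""
    v = np.asarray(stage_means, dtype=float)
    if np.any(v < 0):
        raise ValueError("negative stage means")
    return np.log2((v[1:] + pseudocount) / (v[0] + pseudocount))


def vectors_from_stage_means(means: pd.DataFrame,
                             pseudocount: float = 1.0) -> list[TrendVector]:
    return [TrendVector(g, transform_series(means.loc[g].to_numpy(), pseudocount))
            for g in means.index]


def _assign_matrix(U: np.ndarray, models: np.ndarray, flat_id: int) -> np.ndarray:
    """Assign each 0-prefixed row of U (genes x T) to a model profile.

    Maximizes Pearson correlation; constant rows go to the flat profile;
    exact correlation ties resolve to the lowest profile id.
    """
    Uc = U - U.mean(axis=1, keepdims=True)
    un = np.linalg.norm(Uc, axis=1)
    Mc = models - models.mean(axis=1, keepdims=True)
    mn = np.linalg.norm(Mc, axis=1)
    ok = mn > 0  # flat model is constant: excluded from correlation
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = (Uc @ Mc.T) / np.outer(un, mn)
    corr[:, ~ok] = -np.inf
    best = corr.max(axis=1)
    # lowest-id tie-break within numerical tolerance
    tied = corr >= best[:, None] - 1e-12
    assign = tied.argmax(axis=1)
    assign[un == 0] = flat_id
    return assign


def assign_and_enrich(vectors: list[TrendVector], config: TrendConfig,
                      profiles: list[ProfileResult] | None = None,
                      ) -> tuple[pd.DataFrame, list[ProfileResult]]:
    """Assign genes to model profiles and test profile enrichment.

    Returns (assignment table with columns gene_id/profile_id/correlation,
    list of ProfileResult with observed/expected/p_perm/significant).
    """
    if profiles is None:
        profiles = generate_model_profiles(config)
    if not profiles:
        raise RuntimeError("model profiles not generated")
    models = np.array([p.model for p in profiles], dtype=float)
    flat_id = next(i for i, p in enumerate(profiles)
                   if all(v == 0 for v in p.model))
    gene_ids = [v.gene_id for v in vectors]
    U = np.zeros((len(vectors), config.T))
    for i, v in enumerate(vectors):
        U[i, 1:] = v.values
    assign = _assign_matrix(U, models, flat_id)

    # correlation of each gene with its assigned profile, for the report
    def _corr_row(i: int) -> float:
        u, m_ = U[i], models[assign[i]]
        su, sm = u.std(), m_.std()
        if su == 0 or sm == 0:
            return float("nan")
        return float(np.corrcoef(u, m_)[0, 1])

    table = pd.DataFrame({
        "gene_id": gene_ids,
        "profile_id": [profiles[a].profile_id for a in assign],
        "correlation": [_corr_row(i) for i in range(len(vectors))],
    })
    observed = np.bincount(assign, minlength=len(profiles))

    # permutation null: shuffle each gene's stage order, reassign, count
    rng = spawn_rng(config.seed, "trend-permutation")
    B = config.n_permutations
    ge = np.zeros(len(profiles))
    perm_sum = np.zeros(len(profiles))
    n, T = U.shape
    for _ in range(B):
        idx = np.argsort(rng.random((n, T)), axis=1)
        Up = np.take_along_axis(U, idx, axis=1)
        Up = Up - Up[:, :1]  # re-anchor at the permuted first stage
        counts = np.bincount(_assign_matrix(Up, models, flat_id),
                             minlength=len(profiles))
        ge += counts >= observed
        perm_sum += counts
    for k, prof in enumerate(profiles):
        prof.assigned = [g for g, a in zip(gene_ids, assign) if a == k]
        prof.observed = int(observed[k])
        prof.expected = float(perm_sum[k] / B) if B else float("nan")
        prof.p_perm = float(ge[k] / B) if B else 1.0
        prof.significant = bool(B and prof.p_perm * len(profiles) < config.alpha)
    return table, profiles


def profile_table(profiles: list[ProfileResult]) -> pd.DataFrame:
    return pd.DataFrame([
        {"profile_id": p.profile_id,
         "model": ",".join(str(v) for v in p.model),
         "observed": p.observed, "expected": p.expected,
         "p_perm": p.p_perm, "significant": p.significant}
        for p in profiles
    ])
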
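"""Synthetic 24-hour dietary recall cohorts with known latent dependence.

Recall-level gram amounts are drawn from a Gaussian copula: a latent
multivariate normal vector per meal occurrence, correlated across a
participant's recall days through a shared participant effect, is pushed
through zero-inflated right-skewed margins (lognormal or gamma positive
part). The latent precision matrix is constructed to realise a requested
sparse partial-correlation structure, so downstream network estimation can
be scored against a known truth.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import stats

from .foods import (
    FOOD_GROUPS,
    MAIN_MEALS,
    MEAL_GRAPH_EDGES,
    OCCASIONS,
    REFERENCE_MEAL_INTAKE,
)

RECALL_CSV_HEADER = ("participant_id", "recall_index", "occasion", "food_group", "grams")

__all__ = [
    "GraphSpec",
    "MarginSpec",
    "CohortSpec",
    "RecallDataset",
    "make_precision",
    "latent_correlation",
    "generate_recalls",
    "potsdam_preset",
    "simulate_cohort",
    "InfeasibleGraphError",
]


class InfeasibleGraphError(ValueError):
    """Requested partial-correlation magnitude cannot be realised on the topology."""


@dataclass(frozen=True)
class GraphSpec:
    """A sparse signed conditional-dependence graph over food groups.

    ``edges`` are (i, j, sign) with i < j; ``target_pcor`` is the magnitude
    requested for every true partial correlation.
    """

    n_nodes: int
    topology: str
    edges: tuple[tuple[int, int, int], ...]
    target_pcor: float
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_nodes < 1:
            raise ValueError("n_nodes must be positive")
        if self.topology not in {"hub", "chain", "random", "custom"}:
            raise ValueError(f"unknown topology {self.topology!r}")
        if not 0.0 < self.target_pcor < 1.0:
            raise ValueError("target_pcor must lie strictly between 0 and 1")
        seen: set[tuple[int, int]] = set()
        for i, j, s in self.edges:
            if i == j:
                raise ValueError(f"self-edge on node {i}")
            if not (0 <= i < j < self.n_nodes):
                raise ValueError(f"edge ({i}, {j}) not ordered i < j within range")
            if s not in (-1, 1):
                raise ValueError("edge sign must be +1 or -1")
            if (i, j) in seen:
                raise ValueError(f"duplicate edge ({i}, {j})")
            seen.add((i, j))

    @classmethod
    def hub(cls, n_nodes: int, target_pcor: float, group_size: int = 5,
            sign: int = 1, seed: int = 0) -> "GraphSpec":
        """Disjoint stars: consecutive groups of ``group_size`` nodes, the
        first of each being the hub. Keeping hub degree moderate matters:
        a positive-definite precision matrix cannot give a degree-d hub
        equal partial correlations above 1/sqrt(d)."""
        edges = []
        for start in range(0, n_nodes, group_size):
            stop = min(start + group_size, n_nodes)
            edges.extend((start, k, sign) for k in range(start + 1, stop))
        return cls(n_nodes, "hub", tuple(sorted(edges)), target_pcor, seed)

    @classmethod
    def chain(cls, n_nodes: int, target_pcor: float, sign: int = 1,
              seed: int = 0) -> "GraphSpec":
        edges = tuple((k, k + 1, sign) for k in range(n_nodes - 1))
        return cls(n_nodes, "chain", edges, target_pcor, seed)

    @classmethod
    def random(cls, n_nodes: int, n_edges: int, target_pcor: float,
               seed: int = 0, neg_fraction: float = 0.25) -> "GraphSpec":
        rng = np.random.default_rng(seed)
        pairs = [(i, j) for i in range(n_nodes) for j in range(i + 1, n_nodes)]
        idx = rng.choice(len(pairs), size=n_edges, replace=False)
        edges = tuple(
            (*pairs[k], -1 if rng.random() < neg_fraction else 1)
            for k in sorted(idx)
        )
        return cls(n_nodes, "random", edges, target_pcor, seed)

    @classmethod
    def empty(cls, n_nodes: int, seed: int = 0) -> "GraphSpec":
        return cls(n_nodes, "custom", (), 0.5, seed)

    @classmethod
    def from_labels(cls, labels: Mapping[str, int] | list[str],
                    edges: tuple[tuple[str, str, int], ...],
                    target_pcor: float, seed: int = 0) -> "GraphSpec":
        """Build a custom spec from (label, label, sign) edges."""
        if not isinstance(labels, Mapping):
            labels = {name: k for k, name in enumerate(labels)}
        idx_edges = []
        for a, b, s in edges:
            i, j = labels[a], labels[b]
            idx_edges.append((min(i, j), max(i, j), s))
        return cls(len(labels), "custom", tuple(sorted(set(idx_edges))),
                   target_pcor, seed)

    def adjacency_sign(self) -> np.ndarray:
        A = np.zeros((self.n_nodes, self.n_nodes), dtype=int)
        for i, j, s in self.edges:
            A[i, j] = A[j, i] = s
        return A


def make_precision(spec: GraphSpec, tol: float = 1e-4, max_iter: int = 100) -> np.ndarray:
    """Construct a sparse SPD precision matrix realising ``spec``.

    Off-diagonal support equals the edge list; every realised partial
    correlation -w_ij / sqrt(w_ii w_jj) has the requested sign and a
    magnitude within 0.05 of ``spec.target_pcor`` (to ``tol`` when the
    target is strictly feasible). Edge weights are rescaled iteratively
    under a diagonally dominant diagonal w_ii = 1 + sum_j |w_ij| + 0.01,
    which keeps the matrix positive definite at every step; edges at
    high-degree nodes may saturate slightly below the target, since a
    degree-d node cannot carry equal partial correlations above 1/sqrt(d).
    """
    p = spec.n_nodes
    if not spec.edges:
        return np.eye(p)
    target = spec.target_pcor
    mags = np.full(len(spec.edges), target)
    for _ in range(max_iter):
        omega = np.zeros((p, p))
        for m, (i, j, s) in zip(mags, spec.edges):
            omega[i, j] = omega[j, i] = -s * m
        d = 1.0 + np.abs(omega).sum(axis=1) + 0.01
        np.fill_diagonal(omega, d)
        realized = np.array([
            mags[k] / np.sqrt(d[i] * d[j]) for k, (i, j, _) in enumerate(spec.edges)
        ])
        if np.max(np.abs(realized - target)) < tol:
            return omega
        # damped multiplicative update: the plain fixed point oscillates
        # near the feasibility boundary of high-degree nodes
        mags = mags * (target / realized) ** 0.7
    worst = float(np.max(np.abs(realized - target)))
    if worst <= 0.05:
        return omega
    raise InfeasibleGraphError(
        f"target partial correlation {target} infeasible for topology "
        f"{spec.topology!r}: rescaling did not converge in {max_iter} "
        f"iterations (worst deviation {worst:.4f})"
    )


def latent_correlation(spec: GraphSpec) -> np.ndarray:
    """Latent Gaussian correlation matrix implied by the graph's precision."""
    omega = make_precision(spec)
    sigma = np.linalg.inv(omega)
    d = np.sqrt(np.diag(sigma))
    return sigma / np.outer(d, d)


@dataclass(frozen=True)
class MarginSpec:
    """Zero-inflated skewed margins, one per food group.

    ``zero_probability[j]`` is the point mass at 0 grams; the positive part
    is lognormal (params = meanlog, sdlog) or gamma (params = shape, scale).
    """

    zero_probability: tuple[float, ...]
    family: str = "lognormal"
    params: tuple[tuple[float, float], ...] = ()

    def __post_init__(self) -> None:
        if self.family not in {"lognormal", "gamma"}:
            raise ValueError(f"unknown margin family {self.family!r}")
        if len(self.params) != len(self.zero_probability):
            raise ValueError("params and zero_probability lengths differ")
        for pi0 in self.zero_probability:
            if not 0.0 <= pi0 < 1.0:
                raise ValueError("zero_probability must lie in [0, 1)")
        for a, b in self.params:
            if not (np.isfinite(a) and np.isfinite(b) and b > 0):
                raise ValueError("positive-part parameters must be finite with b > 0")

    @property
    def n_nodes(self) -> int:
        return len(self.zero_probability)

    @classmethod
    def from_moments(cls, means, sds, positive_cv: float = 0.8,
                     max_zero: float = 0.995, family: str = "lognormal") -> "MarginSpec":
        """Calibrate zero mass and positive part to target means/SDs.

        The zero probability absorbs as much of the overdispersion as a
        positive part with coefficient of variation ``positive_cv`` allows;
        when no zero mass is needed the CV is solved exactly from the
        moments instead.
        """
        means = np.asarray(means, dtype=float)
        sds = np.asarray(sds, dtype=float)
        pi0s, params = [], []
        for m, s in zip(means, sds):
            if m <= 0:
                pi0, m1, c = max_zero, 1.0, positive_cv
            else:
                pi0 = 1.0 - (1.0 + positive_cv**2) * m**2 / (s**2 + m**2)
                if pi0 <= 0.0:
                    pi0 = 0.0
                    c = max(s / m, 1e-6)
                elif pi0 > max_zero:
                    pi0 = max_zero
                    c2 = (s**2 + m**2) * (1.0 - pi0) / m**2 - 1.0
                    c = np.sqrt(c2) if c2 > 0 else positive_cv
                else:
                    c = positive_cv
                m1 = m / (1.0 - pi0)
            if family == "lognormal":
                sdlog2 = np.log(1.0 + c**2)
                params.append((float(np.log(m1) - sdlog2 / 2.0), float(np.sqrt(sdlog2))))
            else:
                params.append((float(1.0 / c**2), float(m1 * c**2)))
            pi0s.append(float(pi0))
        return cls(tuple(pi0s), family, tuple(params))

    def positive_quantile(self, u: np.ndarray, node: int) -> np.ndarray:
        a, b = self.params[node]
        if self.family == "lognormal":
            return stats.lognorm.ppf(u, s=b, scale=np.exp(a))
        return stats.gamma.ppf(u, a=a, scale=b)


@dataclass(frozen=True)
class CohortSpec:
    """Study design of a simulated recall cohort."""

    n_participants: int
    recalls_per_participant: Mapping[int, float]
    occasion_labels: tuple[str, ...]
    main_meals: tuple[str, ...]
    meal_graphs: Mapping[str, GraphSpec]
    food_groups: tuple[str, ...]
    participant_effect_sd: float = 0.7
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_participants < 1:
            raise ValueError("n_participants must be positive")
        if len(self.occasion_labels) != 11:
            raise ValueError("a recall day has exactly 11 eating occasions")
        if not set(self.main_meals) <= set(self.occasion_labels):
            raise ValueError("main meals must be occasion labels")
        if set(self.meal_graphs) != set(self.main_meals):
            raise ValueError("meal_graphs keys must equal main_meals")
        p = len(self.food_groups)
        for meal, g in self.meal_graphs.items():
            if g.n_nodes != p:
                raise ValueError(
                    f"graph for {meal!r} has {g.n_nodes} nodes, expected {p}"
                )
        if not all(k in (1, 2, 3) for k in self.recalls_per_participant):
            raise ValueError("recall counts must be in {1, 2, 3}")
        w = sum(self.recalls_per_participant.values())
        if not np.isclose(w, 1.0):
            raise ValueError("recall count probabilities must sum to 1")
        if self.participant_effect_sd < 0:
            raise ValueError("participant_effect_sd must be nonnegative")

    @property
    def within_person_correlation(self) -> float:
        """Latent shared-fraction rho implied by the participant effect SD."""
        s2 = self.participant_effect_sd**2
        return s2 / (1.0 + s2)


@dataclass
class RecallDataset:
    """Long-format recall records plus cohort metadata.

    ``records`` stores only consumed (positive-gram) items; absent
    (occasion, group) combinations are implicit zeros, as in real 24-hour
    recall interviews where only eaten foods are recorded.
    """

    records: pd.DataFrame
    food_groups: tuple[str, ...]
    occasions: tuple[str, ...]
    main_meals: tuple[str, ...]
    provenance: str = "simulated"
    seed: int | None = None

    def __post_init__(self) -> None:
        missing = [c for c in RECALL_CSV_HEADER if c not in self.records.columns]
        if missing:
            raise ValueError(f"records missing columns {missing}")
        if (self.records["grams"] < 0).any():
            raise ValueError("gram amounts must be nonnegative")
        bad = set(self.records["food_group"]) - set(self.food_groups)
        if bad:
            raise ValueError(f"unknown food groups {sorted(bad)[:5]}")
        bad_occ = set(self.records["occasion"]) - set(self.occasions)
        if bad_occ:
            raise ValueError(f"unknown occasions {sorted(bad_occ)}")
        keys = self.records[["participant_id", "recall_index", "occasion", "food_group"]]
        if keys.duplicated().any():
            raise ValueError("duplicate (participant, recall, occasion, group) keys")

    @property
    def n_recall_days(self) -> int:
        return self.records[["participant_id", "recall_index"]].drop_duplicates().shape[0]

    def to_csv(self, path: str | Path) -> None:
        """Write tidy CSV plus a JSON metadata sidecar recording the seed."""
        path = Path(path)
        self.records.loc[:, list(RECALL_CSV_HEADER)].to_csv(path, index=False)
        meta = {
            "food_groups": list(self.food_groups),
            "occasions": list(self.occasions),
            "main_meals": list(self.main_meals),
            "provenance": self.provenance,
            "seed": self.seed,
        }
        path.with_suffix(path.suffix + ".meta.json").write_text(
            json.dumps(meta, indent=1)
        )


def _draw_meal_amounts(rng: np.ndarray, corr: np.ndarray, margins: MarginSpec,
                       day_participant: np.ndarray, n_participants: int,
                       rho: float) -> np.ndarray:
    """Latent-Gaussian draw for one meal across all recall days."""
    p = corr.shape[0]
    L = np.linalg.cholesky(corr)
    u_part = rng.standard_normal((n_participants, p)) @ L.T
    v_day = rng.standard_normal((len(day_participant), p)) @ L.T
    z = np.sqrt(rho) * u_part[day_participant] + np.sqrt(1.0 - rho) * v_day
    U = np.clip(stats.norm.cdf(z), 1e-13, 1.0 - 1e-13)
    pi0 = np.asarray(margins.zero_probability)
    amounts = np.zeros_like(U)
    for j in range(p):
        hit = U[:, j] >= pi0[j]
        if hit.any():
            q = (U[hit, j] - pi0[j]) / (1.0 - pi0[j])
            amounts[hit, j] = margins.positive_quantile(np.clip(q, 1e-13, 1 - 1e-13), j)
    return amounts


def generate_recalls(cohort: CohortSpec,
                     margins: MarginSpec | Mapping[str, MarginSpec],
                     noise_zero_probability: float = 0.97,
                     noise_meanlog: float = 2.7,
                     noise_sdlog: float = 0.8) -> RecallDataset:
    """Simulate a recall cohort under the latent copula model.

    Main-meal amounts follow the meal's Gaussian copula with the
    participant-shared latent fraction; the remaining occasions receive
    independent sparse low-level draws (small snacks without structured
    dependence). Deterministic given ``cohort.seed``.
    """
    rng = np.random.default_rng(cohort.seed)
    groups = np.asarray(cohort.food_groups)
    p = len(groups)

    counts = sorted(cohort.recalls_per_participant)
    probs = [cohort.recalls_per_participant[k] for k in counts]
    n_recalls = rng.choice(counts, size=cohort.n_participants, p=probs)
    day_participant = np.repeat(np.arange(cohort.n_participants), n_recalls)
    day_recall_index = np.concatenate([np.arange(1, k + 1) for k in n_recalls])
    n_days = len(day_participant)
    rho = cohort.within_person_correlation

    frames: list[pd.DataFrame] = []

    def margin_for(meal: str) -> MarginSpec:
        if isinstance(margins, MarginSpec):
            return margins
        return margins[meal]

    for occ in cohort.occasion_labels:
        if occ in cohort.meal_graphs:
            corr = latent_correlation(cohort.meal_graphs[occ])
            amounts = _draw_meal_amounts(
                rng, corr, margin_for(occ), day_participant,
                cohort.n_participants, rho,
            )
        else:
            eaten = rng.random((n_days, p)) >= noise_zero_probability
            amounts = np.zeros((n_days, p))
            if eaten.any():
                amounts[eaten] = rng.lognormal(noise_meanlog, noise_sdlog, eaten.sum())
        rows, cols = np.nonzero(amounts)
        if len(rows):
            frames.append(pd.DataFrame({
                "participant_id": day_participant[rows] + 1,
                "recall_index": day_recall_index[rows],
                "occasion": occ,
                "food_group": groups[cols],
                "grams": amounts[rows, cols],
            }))

    records = pd.concat(frames, ignore_index=True) if frames else pd.DataFrame(
        columns=list(RECALL_CSV_HEADER))
    occ_order = {o: k for k, o in enumerate(cohort.occasion_labels)}
    records = records.sort_values(
        ["participant_id", "recall_index", "occasion", "food_group"],
        key=lambda s: s.map(occ_order) if s.name == "occasion" else s,
        kind="mergesort",
    ).reset_index(drop=True)
    return RecallDataset(
        records=records,
        food_groups=tuple(cohort.food_groups),
        occasions=tuple(cohort.occasion_labels),
        main_meals=tuple(cohort.main_meals),
        provenance="simulated",
        seed=cohort.seed,
    )


def potsdam_preset(seed: int = 0, target_pcor: float = 0.35,
                   participant_effect_sd: float = 0.7,
                   n_participants: int = 814,
                   margin_family: str = "lognormal",
                   ) -> tuple[CohortSpec, dict[str, MarginSpec]]:
    """Ready-made configuration emulating the EPIC-Potsdam recall sub-cohort.

    814 participants, 39 food groups, 11 eating occasions, four main meals
    each with its own latent graph assembled from relations reported for
    that cohort, and margins moment-matched to the cohort's per-meal mean
    and SD gram intakes. The recall-count split (3 participants with one
    recall, 5 with two, the rest with three) follows the cohort design.
    """
    labels = {g: k for k, g in enumerate(FOOD_GROUPS)}
    meal_graphs = {
        meal: GraphSpec.from_labels(labels, MEAL_GRAPH_EDGES[meal],
                                    target_pcor, seed=seed)
        for meal in MAIN_MEALS
    }
    cohort = CohortSpec(
        n_participants=n_participants,
        recalls_per_participant={1: 3 / 814, 2: 5 / 814, 3: 806 / 814},
        occasion_labels=OCCASIONS,
        main_meals=MAIN_MEALS,
        meal_graphs=meal_graphs,
        food_groups=FOOD_GROUPS,
        participant_effect_sd=participant_effect_sd,
        seed=seed,
    )
    margins = {}
    for m_idx, meal in enumerate(MAIN_MEALS):
        means = [REFERENCE_MEAL_INTAKE[g][m_idx][0] for g in FOOD_GROUPS]
        sds = [REFERENCE_MEAL_INTAKE[g][m_idx][1] for g in FOOD_GROUPS]
        margins[meal] = MarginSpec.from_moments(means, sds, family=margin_family)
    return cohort, margins


def simulate_cohort(seed: int = 0, **preset_kwargs) -> RecallDataset:
    """Generate the preset cohort in one call."""
    cohort, margins = potsdam_preset(seed=seed, **preset_kwargs)
    return generate_recalls(cohort, margins)


# --- spec (de)serialisation -------------------------------------------------

def _graph_to_dict(g: GraphSpec) -> dict:
    return {"n_nodes": g.n_nodes, "topology": g.topology,
            "edges": [list(e) for e in g.edges],
            "target_pcor": g.target_pcor, "seed": g.seed}


def _graph_from_dict(d: dict) -> GraphSpec:
    return GraphSpec(d["n_nodes"], d["topology"],
                     tuple(tuple(e) for e in d["edges"]),
                     d["target_pcor"], d.get("seed", 0))


def _margin_to_dict(m: MarginSpec) -> dict:
    return {"zero_probability": list(m.zero_probability), "family": m.family,
            "params": [list(p) for p in m.params]}


def _margin_from_dict(d: dict) -> MarginSpec:
    return MarginSpec(tuple(d["zero_probability"]), d["family"],
                      tuple(tuple(p) for p in d["params"]))


def save_specs(path: str | Path, cohort: CohortSpec,
               margins: MarginSpec | Mapping[str, MarginSpec]) -> None:
    """Write cohort, graph and margin specifications as one YAML config."""
    import yaml

    payload = {
        "cohort": {
            "n_participants": cohort.n_participants,
            "recalls_per_participant": {int(k): float(v) for k, v in
                                        cohort.recalls_per_participant.items()},
            "occasion_labels": list(cohort.occasion_labels),
            "main_meals": list(cohort.main_meals),
            "food_groups": list(cohort.food_groups),
            "participant_effect_sd": cohort.participant_effect_sd,
            "seed": cohort.seed,
        },
        "meal_graphs": {m: _graph_to_dict(g) for m, g in cohort.meal_graphs.items()},
        "margins": (_margin_to_dict(margins) if isinstance(margins, MarginSpec)
                    else {m: _margin_to_dict(s) for m, s in margins.items()}),
    }
    Path(path).write_text(yaml.safe_dump(payload, sort_keys=True))


def load_specs(path: str | Path) -> tuple[CohortSpec, MarginSpec | dict[str, MarginSpec]]:
    """Read back a config written by :func:`save_specs`."""
    import yaml

    payload = yaml.safe_load(Path(path).read_text())
    graphs = {m: _graph_from_dict(d) for m, d in payload["meal_graphs"].items()}
    c = payload["cohort"]
    cohort = CohortSpec(
        n_participants=c["n_participants"],
        recalls_per_participant={int(k): v for k, v in
                                 c["recalls_per_participant"].items()},
        occasion_labels=tuple(c["occasion_labels"]),
        main_meals=tuple(c["main_meals"]),
        meal_graphs=graphs,
        food_groups=tuple(c["food_groups"]),
        participant_effect_sd=c["participant_effect_sd"],
        seed=c["seed"],
    )
    m = payload["margins"]
    if "zero_probability" in m:
        margins: MarginSpec | dict[str, MarginSpec] = _margin_from_dict(m)
    else:
        margins = {meal: _margin_from_dict(d) for meal, d in m.items()}
    return cohort, margins
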
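"""Ground-truth-known synthetic data emulating the study inputs.

Generates (a) a two-class expression matrix whose informative proteins
carry a specified mean shift in pooled-standard-deviation units — an
informative protein with effect size delta has class means ±delta·sigma/2
and common sd sigma, so its population signal-to-noise ratio
(mu1-mu2)/(s1+s2) is exactly delta/2; (b) data from a linear-Gaussian
structural equation model over proteins and the binary class node, with
the true CPDAG returned alongside; (c) Weibull proportional-hazards
survival times with uniform censoring calibrated to a target fraction;
and (d) completely-at-random missingness.  All generators are
deterministic given the seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import networkx as nx
import numpy as np
import pandas as pd

from .io_preprocess import ClinicalTable, InputError, ProteinMatrix
from .pcstable_network import CPDAG, cpdag_from_dag

__all__ = [
    "SurvivalSpec",
    "SyntheticConfig",
    "generate_expression",
    "generate_dag_data",
    "generate_survival",
    "generate_clinical",
    "inject_missing",
]

CLASS_NODE = "class"


@dataclass
class SurvivalSpec:
    """Weibull proportional-hazards configuration.

    ``shape`` > 1 gives an increasing baseline hazard (typical for cancer
    cohorts); ``scale`` is in days.  ``coefficients`` maps covariate names
    to log hazard ratios; ``censoring`` is the target fraction of subjects
    censored by an independent uniform censoring time.
    """

    shape: float = 1.5
    scale: float = 1000.0
    coefficients: dict[str, float] = field(default_factory=dict)
    censoring: float = 0.3

    def __post_init__(self) -> None:
        if not (0 <= self.censoring < 1):
            raise InputError("censoring fraction must be in [0, 1)")
        if self.shape <= 0 or self.scale <= 0:
            raise InputError("Weibull shape and scale must be positive")


@dataclass
class SyntheticConfig:
    """Full specification of a generated dataset.

    ``informative`` lists (protein index, effect size delta) pairs;
    ``dag_spec`` optionally wires proteins and the class node into a DAG of
    (source, target, coefficient) edges.  ``n_per_class`` defaults to the
    near-balanced cohort size of a typical two-subtype RPPA study.
    """

    n_per_class: int = 200
    m_proteins: int = 30
    informative: list[tuple[int, float]] = field(default_factory=list)
    dag_spec: list[tuple[str, str, float]] | None = None
    noise_sd: float = 1.0
    missing_rate: float = 0.0
    survival: SurvivalSpec = field(default_factory=SurvivalSpec)
    seed: int | None = None
    class_labels: tuple[str, str] = ("LUAD", "LUSC")

    def __post_init__(self) -> None:
        if not (0 <= self.missing_rate <= 0.5):
            raise InputError("missing_rate must be in [0, 0.5]")
        for idx, delta in self.informative:
            if not np.isfinite(delta):
                raise InputError(f"non-finite effect size for protein {idx}")
            if not (0 <= idx < self.m_proteins):
                raise InputError(f"informative index {idx} out of range")
        if self.dag_spec is not None:
            g = nx.DiGraph((a, b) for a, b, _ in self.dag_spec)
            if not nx.is_directed_acyclic_graph(g):
                raise InputError("dag_spec contains a directed cycle")

    def protein_names(self) -> list[str]:
        width = len(str(self.m_proteins - 1))
        return [f"P{str(i).zfill(width)}" for i in range(self.m_proteins)]


def generate_expression(cfg: SyntheticConfig) -> tuple[ProteinMatrix, dict]:
    """Two-class expression matrix with planted mean-shift proteins.

    Uninformative proteins are Normal(0, noise_sd²) in both classes;
    informative protein k has class means ±delta_k·noise_sd/2 with common
    sd, giving population SNR delta_k/2.  Returns the matrix and a ground
    truth record (informative names and effect sizes).
    """
    rng = np.random.default_rng(cfg.seed)
    n, m = cfg.n_per_class, cfg.m_proteins
    names = cfg.protein_names()
    X = rng.normal(0.0, cfg.noise_sd, size=(2 * n, m))
    labels = np.array([cfg.class_labels[0]] * n + [cfg.class_labels[1]] * n)
    for idx, delta in cfg.informative:
        shift = delta * cfg.noise_sd / 2.0
        X[:n, idx] += shift
        X[n:, idx] -= shift
    sample_ids = [f"S{str(i).zfill(4)}" for i in range(2 * n)]
    values = pd.DataFrame(X, index=sample_ids, columns=names)
    pm = ProteinMatrix(values, pd.Series(labels, index=sample_ids),
                       classes=cfg.class_labels)
    truth = {
        "informative": {names[idx]: float(d) for idx, d in cfg.informative},
        "population_snr": {names[idx]: float(d) / 2.0 for idx, d in cfg.informative},
    }
    if cfg.missing_rate > 0:
        miss_seed = None if cfg.seed is None else cfg.seed + 1
        pm = inject_missing(pm, cfg.missing_rate, seed=miss_seed)
    return pm, truth


def generate_dag_data(cfg: SyntheticConfig) -> tuple[pd.DataFrame, CPDAG]:
    """Sample a linear-Gaussian structural equation model and its CPDAG.

    Nodes are generated in topological order.  The binary class node is
    drawn from a logistic function of its parents when it has any, and
    Bernoulli(0.5) when it is a root; continuous children of the class
    receive a mean shift of the edge coefficient when the class is 1.
    The returned CPDAG is the Markov equivalence class of the true DAG
    (its v-structures plus Meek closure), the best any CI-based learner
    can recover.
    """
    if cfg.dag_spec is None:
        raise InputError("dag_spec is required for DAG data generation")
    rng = np.random.default_rng(cfg.seed)
    n_total = 2 * cfg.n_per_class
    edges = [(a, b) for a, b, _ in cfg.dag_spec]
    coef = {(a, b): c for a, b, c in cfg.dag_spec}
    g = nx.DiGraph(edges)
    nodes_in_spec = set(g.nodes)
    isolated = [p for p in cfg.protein_names() if p not in nodes_in_spec]
    g.add_nodes_from(isolated)

    data: dict[str, np.ndarray] = {}
    for node in nx.topological_sort(g):
        parents = sorted(g.predecessors(node))
        if node == CLASS_NODE:
            if parents:
                lp = sum(coef[(p, node)] * data[p] for p in parents)
                data[node] = (rng.uniform(size=n_total) < 1 / (1 + np.exp(-lp))).astype(float)
            else:
                data[node] = (rng.uniform(size=n_total) < 0.5).astype(float)
        else:
            mean = np.zeros(n_total)
            for p in parents:
                mean = mean + coef[(p, node)] * data[p]
            data[node] = mean + rng.normal(0.0, cfg.noise_sd, size=n_total)

    order = sorted(g.nodes)
    df = pd.DataFrame({v: data[v] for v in order},
                      index=[f"S{str(i).zfill(4)}" for i in range(n_total)])
    true_cpdag = cpdag_from_dag(edges, nodes=order)
    return df, true_cpdag


def generate_survival(
    cfg: SyntheticConfig, covariates: pd.DataFrame
) -> tuple[np.ndarray, np.ndarray]:
    """Event/censoring times from a Weibull proportional-hazards model.

    The linear predictor is the weighted sum of the named covariates with
    the configured log hazard ratios; T = scale·(-ln U / exp(lp))^(1/shape).
    Censoring is independent Uniform(0, c_max) with c_max calibrated by
    bisection so the expected censored fraction matches the target.
    Returns (observed time, event indicator).
    """
    spec = cfg.survival
    missing = [c for c in spec.coefficients if c not in covariates.columns]
    if missing:
        raise InputError(f"survival covariates absent from the table: {missing}")
    rng = np.random.default_rng(None if cfg.seed is None else cfg.seed + 2)
    n = len(covariates)
    lp = np.zeros(n)
    for name, beta in spec.coefficients.items():
        lp = lp + beta * covariates[name].to_numpy(dtype=float)
    u = rng.uniform(size=n)
    T = spec.scale * (-np.log(u) / np.exp(lp)) ** (1.0 / spec.shape)

    if spec.censoring == 0:
        return T, np.ones(n, dtype=int)

    # E[fraction censored | c_max] = mean_i P(C < T_i) = mean_i min(T_i/c_max, 1)
    def censored_frac(c_max: float) -> float:
        return float(np.mean(np.minimum(T / c_max, 1.0)))

    lo, hi = np.min(T) / 2, np.max(T) * 2
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        if censored_frac(mid) > spec.censoring:
            lo = mid
        else:
            hi = mid
    c_max = 0.5 * (lo + hi)
    C = rng.uniform(0, c_max, size=n)
    events = (T <= C).astype(int)
    return np.minimum(T, C), events


def generate_clinical(cfg: SyntheticConfig, pm: ProteinMatrix) -> ClinicalTable:
    """Clinical table aligned to ``pm``: age, sex, stage, and survival
    endpoints driven by the configured proportional-hazards model.

    Stage (1-4) and age are drawn independently of expression unless named
    in the survival coefficients, in which case they still feed the hazard.
    """
    rng = np.random.default_rng(None if cfg.seed is None else cfg.seed + 3)
    n = pm.n_samples
    frame = pd.DataFrame(index=pm.values.index)
    frame["age_years"] = rng.integers(40, 85, size=n).astype(float)
    frame["sex"] = rng.choice(["male", "female"], size=n)
    frame["race"] = "not reported"
    frame["stage_ordinal"] = rng.choice([1, 2, 3, 4], size=n,
                                        p=[0.5, 0.25, 0.17, 0.08]).astype(float)
    covars = frame.copy()
    covars["sex_male"] = (frame["sex"] == "male").astype(float)
    for col in pm.protein_ids:
        covars[col] = pm.values[col]
    times, events = generate_survival(cfg, covars)
    frame["os_time_days"] = times
    frame["os_status"] = events.astype(float)
    return ClinicalTable(frame)


def inject_missing(
    pm: ProteinMatrix,
    rate: float,
    seed: int | None = None,
    proteins: list[str] | None = None,
) -> ProteinMatrix:
    """Set entries missing completely at random at the given rate.

    With ``proteins`` the missingness is targeted at those columns only
    (useful to exercise the missingness filter); otherwise it applies to
    the whole matrix.
    """
    if not (0 <= rate <= 1):
        raise InputError("rate must be in [0, 1]")
    if rate == 0:
        return pm
    rng = np.random.default_rng(seed)
    values = pm.values.copy()
    cols = proteins if proteins is not None else list(values.columns)
    mask = rng.uniform(size=(len(values), len(cols))) < rate
    block = values[cols].to_numpy(dtype=float)
    block[mask] = np.nan
    values[cols] = block
    return ProteinMatrix(values, pm.class_labels.copy(), pm.classes)
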
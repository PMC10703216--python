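"""Model/Results interface to the marker-discovery pipeline.

:class:`SubtypeSignatureModel` holds a cleaned two-class expression matrix
and the stage parameters; :meth:`~SubtypeSignatureModel.fit` runs
SNR filtering, binary-PSO wrapper selection, and PC-stable network
learning in sequence and returns a :class:`SubtypeSignatureResults`
carrying the three nested marker sets (post-SNR ⊇ post-BPSO ⊇ direct
markers), the learned CPDAG, the fitness trace, and a ``summary()`` table.
Validation statistics (Wilcoxon, Spearman-vs-stage, Cox, Kaplan-Meier)
and embeddings hang off the results object.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import bpso_select, pcstable_network, snr_filter, validation_stats
from .io_preprocess import (
    ClinicalTable,
    InputError,
    ProteinMatrix,
    filter_missing_proteins,
    impute_missing_mean,
    subset_by_classes,
)

logger = logging.getLogger(__name__)

__all__ = ["SubtypeSignatureModel", "SubtypeSignatureResults", "derive_seed"]

CLASS_NODE = "class"


def derive_seed(global_seed: int | None, stage: str) -> int | None:
    """Stable per-stage sub-seed (< 2^31) from a global seed and stage name.

    Lets any stochastic stage be re-run in isolation with the same stream
    it saw inside the full pipeline.
    """
    if global_seed is None:
        return None
    digest = hashlib.sha256(f"{global_seed}:{stage}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)


class SubtypeSignatureModel:
    """Protein-signature discovery for a two-class tumor cohort.

    Parameters
    ----------
    expression
        Complete (imputed) :class:`ProteinMatrix` restricted to two classes.
    snr_threshold
        Minimum |SNR| for a protein to enter the wrapper search (default 0.4).
    bpso_params, fitness_spec
        Swarm and wrapper-fitness settings; defaults follow the reference
        workflow (500 particles, 50 iterations, w=0.5, c1=1, c2=2).
    alpha, ci_method, max_cond
        PC-stable significance level, CI test ("fisher_z" or "g2_disc"),
        and maximum conditioning-set size.
    """

    def __init__(
        self,
        expression: ProteinMatrix,
        snr_threshold: float = 0.4,
        snr_use_abs: bool = True,
        bpso_params: bpso_select.BPSOParams | None = None,
        fitness_spec: bpso_select.FitnessSpec | None = None,
        alpha: float = 0.05,
        ci_method: str = "fisher_z",
        max_cond: int | None = None,
    ):
        if expression.n_missing() > 0:
            raise InputError("expression matrix has missing entries; impute first")
        if expression.classes is None:
            labels = sorted(expression.class_labels.unique())
            if len(labels) != 2:
                raise InputError(f"expected 2 classes, found {labels}")
            expression = ProteinMatrix(
                expression.values, expression.class_labels, (labels[0], labels[1])
            )
        self.expression = expression
        self.snr_threshold = snr_threshold
        self.snr_use_abs = snr_use_abs
        self.bpso_params = bpso_params or bpso_select.BPSOParams()
        self.fitness_spec = fitness_spec or bpso_select.FitnessSpec()
        self.alpha = alpha
        self.ci_method = ci_method
        self.max_cond = max_cond

    @classmethod
    def from_dataframe(
        cls,
        df: pd.DataFrame,
        class_col: str,
        classes: tuple[str, str] | None = None,
        max_missing_frac: float = 0.5,
        **kwargs,
    ) -> "SubtypeSignatureModel":
        """Build from a raw frame (samples as index, one class column).

        Applies the standard preprocessing: subset to the two classes, drop
        proteins missing in more than ``max_missing_frac`` of samples,
        mean-impute the remainder.
        """
        labels = df[class_col].astype(str)
        values = df.drop(columns=[class_col]).apply(pd.to_numeric, errors="coerce")
        pm = ProteinMatrix(values, labels)
        if classes is not None:
            pm = subset_by_classes(pm, list(classes))
        pm, dropped = filter_missing_proteins(pm, max_missing_frac)
        pm, imputed = impute_missing_mean(pm)
        if dropped:
            logger.info("preprocessing dropped %d proteins", len(dropped))
        if imputed:
            logger.info("preprocessing imputed %d proteins", len(imputed))
        return cls(pm, **kwargs)

    def fit(self, seed: int | None = None) -> "SubtypeSignatureResults":
        """Run SNR -> BPSO -> PC-stable and return the fitted results."""
        pm = self.expression

        scores = snr_filter.compute_snr(pm)
        snr_selected = snr_filter.snr_select(
            scores, self.snr_threshold, use_abs=self.snr_use_abs
        )
        logger.info("SNR filter: %d of %d proteins retained",
                    len(snr_selected), pm.n_proteins)
        if len(snr_selected) < 2:
            raise InputError(
                f"SNR filter left {len(snr_selected)} proteins; "
                "lower the threshold or check the class labels"
            )
        filtered = pm.select_proteins(snr_selected)

        params = bpso_select.BPSOParams(
            n_particles=self.bpso_params.n_particles,
            n_iterations=self.bpso_params.n_iterations,
            w=self.bpso_params.w,
            c1=self.bpso_params.c1,
            c2=self.bpso_params.c2,
            v_clamp=self.bpso_params.v_clamp,
            seed=derive_seed(seed, "bpso"),
        )
        selection = bpso_select.run_bpso(filtered, params, self.fitness_spec)
        logger.info("BPSO: %d proteins selected, fitness %.4f",
                    len(selection.selected), selection.fitness)

        bn_input = filtered.select_proteins(selection.selected)
        frame = bn_input.values.copy()
        frame[CLASS_NODE] = (
            bn_input.class_labels == bn_input.classes[1]
        ).astype(float)
        cpdag = pcstable_network.learn_cpdag(
            frame, alpha=self.alpha, max_cond=self.max_cond, method=self.ci_method
        )
        markers = pcstable_network.direct_markers(cpdag, CLASS_NODE)
        logger.info("PC-stable: %d direct markers", len(markers))

        return SubtypeSignatureResults(
            model=self,
            seed=seed,
            snr_scores=scores,
            snr_selected=snr_selected,
            selection=selection,
            cpdag=cpdag,
            direct_marker_edges=markers,
        )


@dataclass
class SubtypeSignatureResults:
    """Fitted signature: nested marker sets, network, and diagnostics."""

    model: SubtypeSignatureModel
    seed: int | None
    snr_scores: pd.DataFrame
    snr_selected: list[str]
    selection: bpso_select.SelectionResult
    cpdag: pcstable_network.CPDAG
    direct_marker_edges: list[tuple[str, str]]

    @property
    def bpso_selected(self) -> list[str]:
        return list(self.selection.selected)

    @property
    def direct_markers(self) -> list[str]:
        return [p for p, _ in self.direct_marker_edges]

    def marker_sets(self) -> dict[str, list[str]]:
        """The three nested selections, outermost first."""
        return {
            "post_snr": list(self.snr_selected),
            "post_bpso": self.bpso_selected,
            "direct_markers": self.direct_markers,
        }

    # ------------------------------------------------------------------
    # downstream characterization

    def group_tests(self, proteins: list[str] | None = None) -> pd.DataFrame:
        """Wilcoxon rank-sum per selected protein between the two classes."""
        pm = self.model.expression
        c1, c2 = pm.classes
        rows = []
        for p in proteins or self.bpso_selected:
            x = pm.values.loc[pm.class_labels == c1, p]
            y = pm.values.loc[pm.class_labels == c2, p]
            res = validation_stats.wilcoxon_rank_sum(x, y)
            rows.append((p, res.statistic, res.p_value, res.n_used))
        return pd.DataFrame(rows, columns=["protein", "rank_sum", "p_value", "n"]) \
            .set_index("protein")

    def stage_correlations(
        self, clinical: ClinicalTable, proteins: list[str] | None = None
    ) -> pd.DataFrame:
        """Spearman correlation of each marker's abundance with stage."""
        pm = self.model.expression
        stage = clinical.data["stage_ordinal"].reindex(pm.values.index)
        rows = []
        for p in proteins or self.bpso_selected:
            res = validation_stats.spearman_corr(pm.values[p], stage)
            rows.append((p, res.effect["rho"], res.p_value, res.n_used))
        return pd.DataFrame(rows, columns=["protein", "rho", "p_value", "n"]) \
            .set_index("protein")

    def cox_table(
        self, clinical: ClinicalTable, covariates: list[str] | None = None
    ) -> pd.DataFrame:
        """Univariate Cox fits for clinical covariates and/or markers.

        ``covariates`` may name canonical clinical fields (``age_years``,
        ``stage_ordinal``, ``sex``) or proteins; sex enters as male=1 vs
        female=0 with the coding stated in the row label.
        """
        pm = self.model.expression
        cdf = clinical.data.reindex(pm.values.index)
        times, events = cdf["os_time_days"], cdf["os_status"]
        rows = []
        for name in covariates or ["age_years", "stage_ordinal", "sex"]:
            if name == "sex":
                covar = cdf["sex"].map({"male": 1.0, "female": 0.0})
                label = "sex (male=1)"
            elif name in cdf.columns:
                covar, label = cdf[name], name
            elif name in pm.values.columns:
                covar, label = pm.values[name], name
            else:
                raise InputError(f"unknown covariate {name!r}")
            res = validation_stats.cox_univariate(times, events, covar, name="x")
            rows.append((label, res.effect["HR"], res.effect["HR_ci_low"],
                         res.effect["HR_ci_high"], res.p_value, res.n_used))
        return pd.DataFrame(
            rows, columns=["variable", "HR", "ci_low", "ci_high", "p_value", "n"]
        ).set_index("variable")

    def km_curves(self, clinical: ClinicalTable, protein: str):
        """Kaplan-Meier curves for a marker split at its median, plus the
        log-rank test."""
        pm = self.model.expression
        cdf = clinical.data.reindex(pm.values.index)
        group = validation_stats.median_split(pm.values[protein])
        return validation_stats.km_logrank(
            cdf["os_time_days"], cdf["os_status"], group
        )

    def pca_report(self, proteins: list[str] | None = None, **kw):
        pm = self.model.expression
        sub = pm.select_proteins(proteins) if proteins else pm
        return validation_stats.pca_report(sub, **kw)

    def tsne_embed(self, proteins: list[str] | None = None, **kw):
        pm = self.model.expression
        sub = pm.select_proteins(proteins) if proteins else pm
        kw.setdefault("seed", derive_seed(self.seed, "tsne") or 0)
        return validation_stats.tsne_embed(sub, **kw)

    # ------------------------------------------------------------------
    # presentation

    def plot_network(self, ax=None):
        """Draw the learned CPDAG; directed edges get arrowheads."""
        import matplotlib.pyplot as plt
        import networkx as nx

        if ax is None:
            _, ax = plt.subplots(figsize=(6, 6))
        g = self.cpdag.to_networkx()
        pos = nx.spring_layout(g, seed=7)
        colors = ["#d62728" if n == CLASS_NODE else "#1f77b4" for n in g.nodes]
        nx.draw_networkx_nodes(g, pos, ax=ax, node_color=colors, node_size=900, alpha=0.85)
        nx.draw_networkx_labels(g, pos, ax=ax, font_size=8, font_color="white")
        directed = [(u, v) for u, v, d in g.edges(data=True) if d["directed"]]
        undirected = {tuple(sorted((u, v))) for u, v, d in g.edges(data=True) if not d["directed"]}
        nx.draw_networkx_edges(g, pos, edgelist=directed, ax=ax, arrows=True, arrowsize=15)
        nx.draw_networkx_edges(g, pos, edgelist=sorted(undirected), ax=ax, arrows=False)
        ax.set_axis_off()
        return ax

    def summary(self) -> str:
        """Human-readable overview of the fitted signature."""
        pm = self.model.expression
        c1, c2 = pm.classes
        n1 = int((pm.class_labels == c1).sum())
        n2 = int((pm.class_labels == c2).sum())
        lines = [
            "Protein signature discovery",
            "=" * 64,
            f"Samples: {pm.n_samples}  ({c1}: {n1}, {c2}: {n2})",
            f"Proteins: {pm.n_proteins}",
            f"Seed: {self.seed}",
            "-" * 64,
            f"SNR filter (|SNR| > {self.model.snr_threshold}): "
            f"{len(self.snr_selected)} proteins",
            f"BPSO wrapper selection: {len(self.bpso_selected)} proteins "
            f"(fitness {self.selection.fitness:.4f}, "
            f"{len(self.selection.trace)} iterations)",
            f"PC-stable (alpha={self.model.alpha}, {self.model.ci_method}): "
            f"{self.cpdag.n_edges()} edges",
            "-" * 64,
            "Direct markers of the class node:",
        ]
        if self.direct_marker_edges:
            for p, kind in self.direct_marker_edges:
                snr = self.snr_scores.loc[p, "snr"]
                lines.append(f"  {p:<16s} {kind:<12s} SNR {snr:+.3f}")
        else:
            lines.append("  (none)")
        lines.append("=" * 64)
        return "\n".join(lines)

    def to_report(self) -> dict:
        """JSON-serializable record of everything non-graphical."""
        return {
            "seed": self.seed,
            "n_samples": self.model.expression.n_samples,
            "n_proteins": self.model.expression.n_proteins,
            "classes": list(self.model.expression.classes),
            "snr_threshold": self.model.snr_threshold,
            "marker_sets": self.marker_sets(),
            "direct_marker_edges": [list(e) for e in self.direct_marker_edges],
            "bpso_fitness": self.selection.fitness,
            "bpso_trace": [float(v) for v in self.selection.trace],
            "network_edges": self.cpdag.edge_table().to_dict(orient="records"),
        }

    def save_report(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_report(), fh, indent=2)
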
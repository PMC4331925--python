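"""Expression-response calls and element/expression association tests.

Per experiment a gene is called up (down) regulated when its fold change
exceeds 1.5 (falls below 1/1.5) AND a two-sided pooled-variance t-test
between arms gives p < 0.05; single-replicate experiments use the fold
change alone. An experiment is valid when at least 100 genes are called.

Enrichment of regulated genes within an element-carrying gene subset is
tested per experiment with the angular (arcsine square-root) two-
proportion z-test, one-sided for enrichment:

    z = (2 asin sqrt(p1) - 2 asin sqrt(p2)) / sqrt(1/n1 + 1/n2)

An element variant is "influential" when the association is significant
in at least `min_experiments` experiments; the default threshold is the
smallest k whose exact binomial tail P(X >= k | N, alpha) is below 0.01
(k = 4 for N = 16 experiments at alpha = 0.05).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats


@dataclass
class ExpressionExperiment:
    """One treatment/control expression experiment on the log2 scale."""

    id: str
    matrix: pd.DataFrame  # genes x samples, log2 scale
    treatment: list[str]
    control: list[str]
    replicated: bool = True

    def __post_init__(self) -> None:
        if not self.treatment or not self.control:
            raise ValueError(f"experiment {self.id}: empty arm")
        if self.matrix.index.duplicated().any():
            raise ValueError(f"experiment {self.id}: duplicate gene ids")


def call_regulation(
    exp: ExpressionExperiment,
    fc_threshold: float = 1.5,
    alpha: float = 0.05,
    welch: bool = False,
) -> pd.DataFrame:
    """Per-gene up/down/none calls for one experiment.

    Returns a frame indexed by gene id with columns ``direction``,
    ``log2_fold_change`` and ``p_value`` (NaN for single-replicate
    experiments, which are called on fold change alone). The fold-change
    gate is strict (> 1.5, i.e. "more than 1.5-fold").
    """
    t = exp.matrix[exp.treatment].to_numpy(dtype=float)
    c = exp.matrix[exp.control].to_numpy(dtype=float)
    n1, n2 = t.shape[1], c.shape[1]
    if exp.replicated and (n1 < 2 or n2 < 2):
        raise ValueError(
            f"experiment {exp.id}: replicated experiment needs >= 2 samples "
            f"per arm"
        )
    lfc = t.mean(axis=1) - c.mean(axis=1)
    if exp.replicated:
        if welch:
            tstat, p = stats.ttest_ind(t, c, axis=1, equal_var=False)
        else:
            tstat, p = stats.ttest_ind(t, c, axis=1, equal_var=True)
        p = np.where(np.isnan(p), 1.0, p)
        sig = p < alpha
    else:
        p = np.full(len(lfc), np.nan)
        sig = np.ones(len(lfc), dtype=bool)
    log_gate = math.log2(fc_threshold)
    direction = np.where(
        (lfc > log_gate) & sig, "up", np.where((lfc < -log_gate) & sig,
                                               "down", "none")
    )
    return pd.DataFrame(
        {"direction": direction, "log2_fold_change": lfc, "p_value": p},
        index=exp.matrix.index,
    )


def validate_experiment(calls: pd.DataFrame, min_regulated: int = 100) -> bool:
    """True iff at least ``min_regulated`` genes were called up or down."""
    return int((calls["direction"] != "none").sum()) >= min_regulated


def consensus_regulated_genes(
    all_calls: Sequence[pd.DataFrame], min_experiments: int = 4
) -> tuple[set[str], set[str]]:
    """Genes called up (down) in at least ``min_experiments`` experiments.

    A gene may appear in both lists (the two criteria are independent).
    """
    if len(all_calls) < min_experiments:
        raise ValueError("fewer experiments than min_experiments")
    up_counts: dict[str, int] = {}
    down_counts: dict[str, int] = {}
    for calls in all_calls:
        for gid in calls.index[calls["direction"] == "up"]:
            up_counts[gid] = up_counts.get(gid, 0) + 1
        for gid in calls.index[calls["direction"] == "down"]:
            down_counts[gid] = down_counts.get(gid, 0) + 1
    up = {g for g, n in up_counts.items() if n >= min_experiments}
    down = {g for g, n in down_counts.items() if n >= min_experiments}
    return up, down


@dataclass(frozen=True)
class ProportionTestResult:
    p1: float
    p2: float
    n1: int
    n2: int
    z_statistic: float
    p_value: float  # one-sided upper tail (tests p1 > p2)
    significant: bool


def arcsine_proportion_test(
    k1: int, n1: int, k2: int, n2: int, alpha: float = 0.05
) -> ProportionTestResult:
    """Angular-transform two-proportion z-test, one-sided for p1 > p2."""
    if n1 < 1 or n2 < 1:
        raise ValueError("group sizes must be >= 1")
    if not (0 <= k1 <= n1 and 0 <= k2 <= n2):
        raise ValueError("counts must satisfy 0 <= k <= n")
    p1, p2 = k1 / n1, k2 / n2
    z = (2 * math.asin(math.sqrt(p1)) - 2 * math.asin(math.sqrt(p2))) / (
        math.sqrt(1 / n1 + 1 / n2)
    )
    p = float(stats.norm.sf(z))
    return ProportionTestResult(p1, p2, n1, n2, z, p, p < alpha)


def binomial_tail(N: int, k: int, p: float) -> float:
    """Exact upper tail P(X >= k) = sum_{j=k}^{N} C(N,j) p^j (1-p)^(N-j)."""
    if not 0 <= k <= N:
        raise ValueError("need 0 <= k <= N")
    if not 0 <= p <= 1:
        raise ValueError("need 0 <= p <= 1")
    if k == 0:
        return 1.0
    total = math.fsum(
        math.comb(N, j) * p**j * (1 - p) ** (N - j) for j in range(k, N + 1)
    )
    return float(min(1.0, total))


def resolve_min_experiments(
    n_experiments: int, alpha: float = 0.05, tail_bound: float = 0.01
) -> int:
    """Smallest k with binomial_tail(N, k, alpha) < tail_bound."""
    for k in range(n_experiments + 1):
        if binomial_tail(n_experiments, k, alpha) < tail_bound:
            return k
    return n_experiments + 1  # unreachable in practice


@dataclass
class MetaAssociation:
    """Cross-experiment association verdict for one element variant."""

    element_id: str
    results: list[ProportionTestResult] = field(default_factory=list)
    experiment_ids: list[str] = field(default_factory=list)
    min_experiments: int = 4

    @property
    def significant_flags(self) -> list[bool]:
        return [r.significant for r in self.results]

    @property
    def n_significant(self) -> int:
        return sum(self.significant_flags)

    @property
    def influential(self) -> bool:
        return self.n_significant >= self.min_experiments


def meta_association(
    subset: set[str],
    experiments_calls: Sequence[tuple[str, pd.DataFrame]],
    alpha: float = 0.05,
    min_experiments: int | None = None,
    direction: str = "up",
    element_id: str = "element",
) -> MetaAssociation:
    """Per-experiment enrichment of regulated genes in an element subset.

    For every experiment the regulated fraction within the subset
    (k1/n1) is compared with the fraction among all probed genes (k2/n2;
    the subset stays inside the "all" group). Influential means
    significant in >= min_experiments experiments; by default
    min_experiments is resolved from the exact binomial tail bound.
    """
    if not subset:
        raise ValueError("empty element gene subset")
    if min_experiments is None:
        min_experiments = resolve_min_experiments(len(experiments_calls), alpha)
    meta = MetaAssociation(element_id=element_id,
                           min_experiments=min_experiments)
    for exp_id, calls in experiments_calls:
        universe = calls.index
        in_subset = universe.isin(subset)
        regulated = (calls["direction"] == direction).to_numpy()
        n1 = int(in_subset.sum())
        if n1 == 0:
            # element genes absent from this platform: cannot test
            meta.results.append(
                ProportionTestResult(0.0, 0.0, 1, 1, 0.0, 1.0, False)
            )
            meta.experiment_ids.append(exp_id)
            continue
        k1 = int((regulated & in_subset).sum())
        k2 = int(regulated.sum())
        n2 = len(universe)
        meta.results.append(arcsine_proportion_test(k1, n1, k2, n2, alpha))
        meta.experiment_ids.append(exp_id)
    return meta


def _pct(numer: int, denom: int) -> float | None:
    """Percentage rounded half-up to one decimal; None for 0 denominators."""
    if denom == 0:
        return None
    return math.floor(1000 * numer / denom + 0.5) / 10


@dataclass(frozen=True)
class AssociationSummary:
    """Per-variant genome-wide tallies: genes with the element (Z),
    regulated among them (X), conserved-element among those (Y)."""

    Z: int
    X_up: int
    Y_up: int
    X_down: int
    Y_down: int
    pct_up: float | None
    pct_up_conserved: float | None
    pct_down: float | None
    pct_down_conserved: float | None


def summarize_association(
    Z: int, X_up: int, Y_up: int, X_down: int = 0, Y_down: int = 0
) -> AssociationSummary:
    """Tally percentages 100*X/Z and 100*Y/X to one decimal place."""
    if not (Y_up <= X_up <= Z and Y_down <= X_down <= Z):
        raise ValueError("counts must satisfy Y <= X <= Z")
    return AssociationSummary(
        Z=Z,
        X_up=X_up,
        Y_up=Y_up,
        X_down=X_down,
        Y_down=Y_down,
        pct_up=_pct(X_up, Z),
        pct_up_conserved=_pct(Y_up, X_up),
        pct_down=_pct(X_down, Z),
        pct_down_conserved=_pct(Y_down, X_down),
    )


# ---------------------------------------------------------------------------
# TSV I/O for expression panels


def read_expression_panel(matrix_paths, design_path) -> list[ExpressionExperiment]:
    """Load experiments from TSV matrices plus a design table.

    Design columns: sample_id, experiment_id, arm (treatment|control).
    ``matrix_paths`` maps experiment_id to its matrix TSV (first column
    gene id, header sample ids).
    """
    design = pd.read_csv(design_path, sep="\t")
    experiments = []
    for exp_id, grp in design.groupby("experiment_id", sort=True):
        mat = pd.read_csv(matrix_paths[exp_id], sep="\t", index_col=0)
        treat = grp.loc[grp["arm"] == "treatment", "sample_id"].tolist()
        ctrl = grp.loc[grp["arm"] == "control", "sample_id"].tolist()
        experiments.append(
            ExpressionExperiment(
                id=str(exp_id),
                matrix=mat,
                treatment=treat,
                control=ctrl,
                replicated=len(treat) > 1 and len(ctrl) > 1,
            )
        )
    return experiments
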
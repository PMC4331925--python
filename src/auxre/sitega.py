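"""SiteGA: a discriminant of locally positioned dinucleotides (LPD).

An LPD feature is the frequency of one dinucleotide inside a short
positional window of the analysed region. A genetic algorithm selects a
subset of K features that best separates site sequences from decoys under
the Fisher linear discriminant; the discriminant direction on the winning
subset defines the recognition score, min-max normalised to [0, 1].

The analysed region is the 25-nt frame [-12;+13] around the centrally
positioned TGTCNN core (core occupying [-3;+3]), i.e. the core hexamer
starts 9 nt into the frame.

The combined AuxRE_P&S predictor calls a site only where both the oPWM
and the SiteGA score pass their calibrated thresholds (0.78 / 0.936) at
the same TGTCNN anchor and strand.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .opwm import (
    CORE_WIDTH,
    DINUCS,
    PWMModel,
    TrainingAlignment,
    dinucleotide_shuffle,
    oriented_window,
    score_window_opwm,
)
from .sequence_core import (
    SequenceRecord,
    SiteHit,
    parse_iupac,
    scan_consensus,
)

logger = logging.getLogger(__name__)

#: geometry of the scored frame: 25 nt, core hexamer starting 9 nt in
FRAME_LENGTH = 25
FRAME_UPSTREAM = 9

DEFAULT_GA_PARAMS = {
    "population": 100,
    "generations": 200,
    "mutation_rate": 0.02,
    "tournament": 3,
}


@dataclass(frozen=True)
class LPDFeature:
    """Frequency of `dinucleotide` among starts in character window [a,b).

    The window spans characters a..b-1; dinucleotide start positions
    a..b-2 are counted and divided by the b-a-1 available starts.
    """

    dinucleotide: str
    a: int
    b: int

    def value(self, seq: str) -> float:
        n = self.b - self.a - 1
        count = 0
        for i in range(self.a, self.b - 1):
            if seq[i : i + 2] == self.dinucleotide:
                count += 1
        return count / n


def enumerate_lpd_features(region_length: int, max_window: int) -> list[LPDFeature]:
    """All LPD features with character-window span 2..max_window.

    For span w there are region_length - w + 1 windows, hence
    16 * sum_w (L - w + 1) features in total.
    """
    if region_length < 2:
        raise ValueError("region_length must be >= 2")
    if not 2 <= max_window <= region_length:
        raise ValueError("max_window must be in [2, region_length]")
    feats = []
    for w in range(2, max_window + 1):
        for a in range(region_length - w + 1):
            for dn in DINUCS:
                feats.append(LPDFeature(dn, a, a + w))
    return feats


def feature_matrix(seqs: list[str], features: list[LPDFeature]) -> np.ndarray:
    """n_seqs x n_features LPD value matrix (vectorised by dinucleotide)."""
    n, length = len(seqs), len(seqs[0])
    # indicator[d, s, i] = 1 if seq s has dinucleotide d at start i
    codes = {d: k for k, d in enumerate(DINUCS)}
    ind = np.zeros((16, n, length - 1), dtype=np.float64)
    for s, seq in enumerate(seqs):
        for i in range(length - 1):
            k = codes.get(seq[i : i + 2])
            if k is not None:
                ind[k, s, i] = 1.0
    cum = np.concatenate(
        [np.zeros((16, n, 1)), np.cumsum(ind, axis=2)], axis=2
    )
    X = np.empty((n, len(features)))
    for j, f in enumerate(features):
        k = codes[f.dinucleotide]
        X[:, j] = (cum[k, :, f.b - 1] - cum[k, :, f.a]) / (f.b - f.a - 1)
    return X


@dataclass
class SiteGAModel:
    """Fisher discriminant over a GA-selected set of LPD features."""

    features: list[LPDFeature]
    weights: np.ndarray
    intercept: float
    region_length: int
    score_min: float
    score_max: float
    threshold: float = 0.936
    model_id: str = "SiteGA"
    seed: int | None = None
    separable: bool = True
    core_in_window: int = FRAME_UPSTREAM

    def raw_score(self, window: str) -> float:
        vals = np.array([f.value(window) for f in self.features])
        return float(vals @ self.weights + self.intercept)

    def to_json(self) -> str:
        return json.dumps(
            {
                "model_id": self.model_id,
                "region_length": self.region_length,
                "core_in_window": self.core_in_window,
                "features": [
                    [f.dinucleotide, f.a, f.b] for f in self.features
                ],
                "weights": self.weights.tolist(),
                "intercept": self.intercept,
                "score_min": self.score_min,
                "score_max": self.score_max,
                "threshold": self.threshold,
                "seed": self.seed,
                "separable": self.separable,
            },
            indent=1,
        )

    @classmethod
    def from_json(cls, text: str) -> "SiteGAModel":
        d = json.loads(text)
        return cls(
            features=[LPDFeature(dn, a, b) for dn, a, b in d["features"]],
            weights=np.asarray(d["weights"]),
            intercept=d["intercept"],
            region_length=d["region_length"],
            score_min=d["score_min"],
            score_max=d["score_max"],
            threshold=d["threshold"],
            model_id=d["model_id"],
            seed=d["seed"],
            separable=d["separable"],
            core_in_window=d.get("core_in_window", FRAME_UPSTREAM),
        )

    def to_tsv(self) -> str:
        lines = ["dinucleotide\ta\tb\tweight"]
        for f, w in zip(self.features, self.weights):
            lines.append(f"{f.dinucleotide}\t{f.a}\t{f.b}\t{w:.10g}")
        return "\n".join(lines) + "\n"


def _fisher_stats(
    Xp: np.ndarray, Xn: np.ndarray, ridge: float = 1e-6
) -> tuple[np.ndarray, float]:
    """Fisher direction and criterion J = (mu1-mu2)' Sw^-1 (mu1-mu2)."""
    mu1, mu2 = Xp.mean(axis=0), Xn.mean(axis=0)
    n1, n2 = len(Xp), len(Xn)
    s1 = np.cov(Xp, rowvar=False, bias=False) if n1 > 1 else np.zeros(
        (Xp.shape[1], Xp.shape[1])
    )
    s2 = np.cov(Xn, rowvar=False, bias=False) if n2 > 1 else np.zeros(
        (Xn.shape[1], Xn.shape[1])
    )
    sw = ((n1 - 1) * s1 + (n2 - 1) * s2) / max(n1 + n2 - 2, 1)
    sw = sw + ridge * np.eye(sw.shape[0])
    diff = mu1 - mu2
    w = np.linalg.solve(sw, diff)
    return w, float(diff @ w)


def train_sitega(
    positives: list[str],
    negatives: list[str] | None = None,
    K: int = 30,
    ga_params: dict | None = None,
    max_window: int = 6,
) -> SiteGAModel:
    """GA selection of K LPD features + Fisher discriminant weights.

    The GA chromosome is a K-subset of the feature universe; fitness is
    the Fisher criterion of the two classes in the selected subspace.
    ``negatives`` default to 3x dinucleotide-shuffled positives. The run
    is reproducible given ``ga_params['seed']`` (mandatory).
    """
    params = dict(DEFAULT_GA_PARAMS)
    if ga_params:
        params.update(ga_params)
    if "seed" not in params:
        raise ValueError("ga_params must include a seed")
    rng = np.random.default_rng(params["seed"])

    if not positives:
        raise ValueError("empty positive class")
    region_length = len(positives[0])
    if negatives is None:
        negatives = [
            dinucleotide_shuffle(p, rng) for p in positives for _ in range(3)
        ]
    if not negatives:
        raise ValueError("empty negative class")

    features = enumerate_lpd_features(region_length, max_window)
    Xp = feature_matrix(positives, features)
    Xn = feature_matrix(negatives, features)

    var = np.concatenate([Xp, Xn]).var(axis=0)
    usable = np.flatnonzero(var > 0)
    if usable.size == 0:
        raise ValueError("degenerate input: all LPD features have zero variance")
    if usable.size < K:
        K = usable.size
    if sorted(positives) == sorted(negatives):
        warnings.warn("positive and negative classes are identical; "
                      "discriminant is at chance (non-separable)")

    pop_size = params["population"]
    gens = params["generations"]
    mut = params["mutation_rate"]
    tour = params["tournament"]

    def random_subset():
        return np.sort(rng.choice(usable, size=K, replace=False))

    def fitness(idx: np.ndarray) -> float:
        _, J = _fisher_stats(Xp[:, idx], Xn[:, idx])
        return J

    population = [random_subset() for _ in range(pop_size)]
    fits = np.array([fitness(ind) for ind in population])

    for _ in range(gens):
        order = np.argsort(fits)[::-1]
        new_pop = [population[order[0]]]  # elitism
        while len(new_pop) < pop_size:
            # tournament selection of two parents
            parents = []
            for _ in range(2):
                contenders = rng.integers(0, pop_size, size=tour)
                parents.append(population[contenders[np.argmax(fits[contenders])]])
            # one-point crossover on the sorted index sets
            cut = rng.integers(1, K)
            child = np.unique(
                np.concatenate([parents[0][:cut], parents[1][cut:]])
            )
            # repair to size K with unused random features
            if child.size < K:
                pool = np.setdiff1d(usable, child, assume_unique=False)
                extra = rng.choice(pool, size=K - child.size, replace=False)
                child = np.sort(np.concatenate([child, extra]))
            # per-gene mutation: swap a feature for a random unused one
            mask = rng.random(K) < mut
            if mask.any():
                pool = np.setdiff1d(usable, child)
                for pos in np.flatnonzero(mask):
                    if pool.size == 0:
                        break
                    j = rng.integers(pool.size)
                    child[pos], pool[j] = pool[j], child[pos]
                child = np.sort(child)
            new_pop.append(child)
        population = new_pop
        fits = np.array([fitness(ind) for ind in population])

    best_idx = population[int(np.argmax(fits))]
    w, J = _fisher_stats(Xp[:, best_idx], Xn[:, best_idx])
    mu_mid = (Xp[:, best_idx].mean(axis=0) + Xn[:, best_idx].mean(axis=0)) / 2
    intercept = -float(mu_mid @ w)
    train_scores = np.concatenate(
        [Xp[:, best_idx] @ w + intercept, Xn[:, best_idx] @ w + intercept]
    )
    smin, smax = float(train_scores.min()), float(train_scores.max())
    if smax - smin < 1e-12:
        smax = smin + 1.0
    return SiteGAModel(
        features=[features[i] for i in best_idx],
        weights=w,
        intercept=intercept,
        region_length=region_length,
        score_min=smin,
        score_max=smax,
        seed=params["seed"],
        separable=bool(J > 1e-9),
    )


def score_window_sitega(model: SiteGAModel, window: str) -> float:
    """Min-max-normalised discriminant score, clamped to [0, 1].

    Windows containing ``N`` score 0.0.
    """
    if len(window) != model.region_length:
        raise ValueError(
            f"window length {len(window)} != region length "
            f"{model.region_length}"
        )
    if "N" in window:
        return 0.0
    raw = model.raw_score(window)
    s = (raw - model.score_min) / (model.score_max - model.score_min)
    return float(min(1.0, max(0.0, s)))


def training_frames(alignment: TrainingAlignment) -> list[str]:
    """Extract the 25-nt [-12;+13] frames from a core-centred alignment."""
    start = alignment.core_offset - FRAME_UPSTREAM
    if start < 0 or start + FRAME_LENGTH > alignment.length:
        raise ValueError("alignment flanks too short for the 25-nt frame")
    return [r[start : start + FRAME_LENGTH] for r in alignment.records]


def scan_sitega(
    record: SequenceRecord, model: SiteGAModel, threshold: float | None = None
) -> list[SiteHit]:
    """Anchor-based SiteGA scan over TGTCNN anchors, both strands."""
    if threshold is None:
        threshold = model.threshold
    anchor = parse_iupac("TGTCNN")
    hits = []
    for h in scan_consensus(record, anchor, ("+", "-")):
        win = oriented_window(
            record.seq, h.start, h.strand, model.core_in_window,
            model.region_length,
        )
        if win is None:
            continue
        s = score_window_sitega(model, win)
        if s >= threshold:
            hits.append(
                SiteHit(record.id, h.start, CORE_WIDTH, h.strand, s,
                        model.model_id)
            )
    return hits


def predict_auxre_ps(
    record: SequenceRecord,
    opwm_model: PWMModel,
    sga_model: SiteGAModel,
    thresholds: tuple[float, float] = (0.78, 0.936),
    model_id: str = "AuxRE_P&S",
) -> list[SiteHit]:
    """Sites called by BOTH models at the same TGTCNN anchor and strand.

    The hit score is the smaller of the two normalised model scores;
    anchors whose scoring window runs off the sequence are skipped.
    """
    t_pwm, t_sga = thresholds
    anchor = parse_iupac("TGTCNN")
    hits = []
    for h in scan_consensus(record, anchor, ("+", "-")):
        win_p = oriented_window(
            record.seq, h.start, h.strand, opwm_model.core_in_window,
            opwm_model.window_length,
        )
        win_s = oriented_window(
            record.seq, h.start, h.strand, sga_model.core_in_window,
            sga_model.region_length,
        )
        if win_p is None or win_s is None:
            logger.debug(
                "anchor %s:%d%s skipped: window beyond sequence end",
                record.id, h.start, h.strand,
            )
            continue
        sp = score_window_opwm(opwm_model, win_p)
        if sp < t_pwm:
            continue
        ss = score_window_sitega(sga_model, win_s)
        if ss < t_sga:
            continue
        hits.append(
            SiteHit(record.id, h.start, CORE_WIDTH, h.strand, min(sp, ss),
                    model_id)
        )
    return hits


def calibrate_joint_thresholds(
    opwm_model: PWMModel,
    sga_model: SiteGAModel,
    positive_regions: list[SequenceRecord],
    target_fraction: float,
) -> tuple[float, float]:
    """Joint (oPWM, SiteGA) thresholds covering >= target_fraction regions.

    A region is covered when at least one TGTCNN anchor passes BOTH
    thresholds. Candidate threshold pairs are matched per-region-maximum
    quantiles of the two score distributions; the pair with the highest
    thresholds whose joint coverage reaches the target is returned.
    """
    if not 0 < target_fraction <= 1:
        raise ValueError("target_fraction must be in (0, 1]")
    anchor = parse_iupac("TGTCNN")
    per_region: list[list[tuple[float, float]]] = []
    for region in positive_regions:
        pairs = []
        for h in scan_consensus(region, anchor, ("+", "-")):
            win_p = oriented_window(
                region.seq, h.start, h.strand, opwm_model.core_in_window,
                opwm_model.window_length,
            )
            win_s = oriented_window(
                region.seq, h.start, h.strand, sga_model.core_in_window,
                sga_model.region_length,
            )
            if win_p is None or win_s is None:
                continue
            pairs.append(
                (
                    score_window_opwm(opwm_model, win_p),
                    score_window_sitega(sga_model, win_s),
                )
            )
        per_region.append(pairs)
    if not any(per_region):
        raise ValueError("no scorable anchors in any positive region")
    n = len(per_region)
    max_p = sorted(
        (max(s for s, _ in pr) for pr in per_region if pr), reverse=True
    )
    max_s = sorted(
        (max(s for _, s in pr) for pr in per_region if pr), reverse=True
    )
    k0 = max(1, int(np.ceil(target_fraction * n)))
    for k in range(k0, len(max_p) + 1):
        t_p, t_s = max_p[k - 1], max_s[k - 1]
        covered = sum(
            any(sp >= t_p and ss >= t_s for sp, ss in pr)
            for pr in per_region
        )
        if covered / n >= target_fraction:
            return t_p, t_s
    # fall back to the loosest matched pair
    return max_p[-1], max_s[-1]


# ---------------------------------------------------------------------------
# LPD pair dependencies


@dataclass
class DependencyProfile:
    """Per-position counts of significant LPD-pair correlations."""

    region_length: int
    counts: np.ndarray  # per position, count of significant pairs covering it
    positive_pairs: list = field(default_factory=list)
    negative_pairs: list = field(default_factory=list)

    @property
    def n_significant(self) -> int:
        return len(self.positive_pairs) + len(self.negative_pairs)


def lpd_dependency_profile(
    alignment, alpha: float = 0.05, max_window: int = 4
) -> DependencyProfile:
    """Significant pairwise Pearson correlations between LPD features.

    ``alignment`` may be a TrainingAlignment (its 25-nt core frames are
    analysed) or a list of equal-length strings. A pair is recorded when
    its two-sided correlation p-value is below ``alpha``; each significant
    pair increments the count of every position covered by either of its
    windows.
    """
    if isinstance(alignment, TrainingAlignment):
        seqs = training_frames(alignment)
    else:
        seqs = list(alignment)
    if len(seqs) < 5:
        raise ValueError("need at least 5 records")
    length = len(seqs[0])
    features = enumerate_lpd_features(length, max_window)
    X = feature_matrix(seqs, features)
    var = X.var(axis=0)
    keep = np.flatnonzero(var > 0)
    prof = DependencyProfile(region_length=length, counts=np.zeros(length))
    if keep.size < 2:
        return prof
    Xk = X[:, keep]
    n = len(seqs)
    R = np.corrcoef(Xk, rowvar=False)
    iu, ju = np.triu_indices(keep.size, k=1)
    r = np.clip(R[iu, ju], -1.0, 1.0)
    with np.errstate(divide="ignore"):
        t = r * np.sqrt((n - 2) / np.maximum(1e-300, 1 - r * r))
    p = 2 * stats.t.sf(np.abs(t), df=n - 2)
    p[np.abs(r) >= 1.0] = 0.0
    sig = np.flatnonzero(p < alpha)
    for s in sig:
        fi = features[keep[iu[s]]]
        fj = features[keep[ju[s]]]
        entry = (fi, fj, float(r[s]), float(p[s]))
        (prof.positive_pairs if r[s] > 0 else prof.negative_pairs).append(entry)
        lo = min(fi.a, fj.a)
        covered = np.zeros(length, dtype=bool)
        covered[fi.a : fi.b] = True
        covered[fj.a : fj.b] = True
        prof.counts[covered] += 1
        del lo
    return prof
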
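"""MotiGA: genetic-algorithm discovery of coupling motifs on AuxRE flanks.

The TGTCNN core of each training record is masked so the core consensus
cannot dominate the search; the GA then optimises one motif instance
placement per record (either flank, either strand) to maximise the
Kullback discrete information content (KDIC) of the induced frequency
matrix. Successive motifs are found by deflation: the instances of each
discovered motif are masked before the next search.

Per-word score p-values under the i.i.d. background are computed exactly
by dynamic-programming convolution of the per-column score distributions,
and a motif's score threshold is set by a critical p-value.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .opwm import LETTER_INDEX, LETTERS, TrainingAlignment, CORE_WIDTH
from .sequence_core import reverse_complement

MASK = "#"

DEFAULT_GA_PARAMS = {
    "population": 80,
    "generations": 80,
    "mutation_rate": 0.05,
    "tournament": 3,
}


@dataclass
class MaskedAlignment:
    """Training records with the core hexamer (and any deflated instances)
    replaced by a mask character; originals retained for round-trips."""

    records: list[str]
    originals: list[str]
    core_offset: int

    @property
    def length(self) -> int:
        return len(self.records[0])

    def __len__(self) -> int:
        return len(self.records)

    def unmask(self) -> list[str]:
        return list(self.originals)


def mask_core(alignment: TrainingAlignment) -> MaskedAlignment:
    """Replace the 6-nt TGTCNN core of every record by mask characters."""
    lo = alignment.core_offset
    hi = lo + CORE_WIDTH
    masked = [r[:lo] + MASK * CORE_WIDTH + r[hi:] for r in alignment.records]
    return MaskedAlignment(
        records=masked,
        originals=list(alignment.records),
        core_offset=alignment.core_offset,
    )


def kdic(freq: np.ndarray, background: np.ndarray) -> float:
    """Kullback information content, bits per position.

    (1/W) * sum_cols sum_letters f * log2(f / b), with 0*log(0/b) = 0.
    """
    freq = np.asarray(freq, dtype=float)
    background = np.asarray(background, dtype=float)
    if np.any(background <= 0):
        raise ValueError("background probabilities must be strictly positive")
    width = freq.shape[1]
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = freq * np.log2(freq / background[:, None])
    terms[freq == 0] = 0.0
    return float(terms.sum() / width)


@dataclass
class MotifMatrix:
    """A discovered coupling-motif frequency matrix with its instances."""

    width: int
    freq: np.ndarray  # 4 x width
    weights: np.ndarray  # 4 x width log2 ratios (smoothed)
    background: np.ndarray
    kdic: float
    motif_id: str = "motif"
    critical_p: float | None = None
    score_threshold: float | None = None
    # per-record (record_index, position, strand, score, p, passed)
    instances: list = field(default_factory=list)

    @property
    def consensus(self) -> str:
        return "".join(LETTERS[i] for i in self.freq.argmax(axis=0))

    def word_score(self, word: str) -> float:
        return float(
            sum(self.weights[LETTER_INDEX[c], j] for j, c in enumerate(word))
        )

    def to_meme_text(self) -> str:
        lines = [
            "MEME version 4",
            "",
            "ALPHABET= ACGT",
            "",
            f"MOTIF {self.motif_id} {self.consensus}",
            (
                f"letter-probability matrix: alength= 4 w= {self.width} "
                f"nsites= {len(self.instances)} E= 0"
            ),
        ]
        for col in self.freq.T:
            lines.append(" " + " ".join(f"{v:.6f}" for v in col))
        return "\n".join(lines) + "\n"


# ---------------------------------------------------------------------------
# exact score distribution / p-values


def _score_distribution(matrix: MotifMatrix, resolution: float = 1e-4):
    """Discretised distribution of word scores under the i.i.d. background.

    Returns (base, delta, probs) where achievable total scores are
    base + k*delta and probs[k] their background probability; delta is
    ``resolution`` of the full score range.
    """
    w = matrix.weights
    bg = matrix.background
    col_min = w.min(axis=0)
    col_max = w.max(axis=0)
    base = float(col_min.sum())
    rng_total = float(col_max.sum()) - base
    if rng_total <= 0:
        return base, 1.0, np.array([1.0])
    delta = rng_total * resolution
    nbins = int(round(rng_total / delta)) + 1
    dist = np.zeros(1)
    for j in range(matrix.width):
        bins = np.rint((w[:, j] - col_min[j]) / delta).astype(int)
        col = np.zeros(bins.max() + 1)
        for a in range(4):
            col[bins[a]] += bg[a]
        dist = np.convolve(dist if dist.size > 1 else np.array([1.0]), col)
    # numerical safety: clip and renormalise
    dist = np.clip(dist, 0, None)
    dist /= dist.sum()
    del nbins
    return base, delta, dist


def word_score_pvalue(
    matrix: MotifMatrix,
    score: float,
    background: np.ndarray | None = None,
    resolution: float = 1e-4,
) -> float:
    """P(random word scores >= score) under the i.i.d. background.

    Monotone nonincreasing in ``score``; a score above the achievable
    maximum returns the probability mass of the argmax word set (never 0:
    floored at the smallest positive float). A score at or below the
    achievable minimum returns 1.
    """
    if background is not None:
        matrix = MotifMatrix(
            width=matrix.width,
            freq=matrix.freq,
            weights=matrix.weights,
            background=np.asarray(background, dtype=float),
            kdic=matrix.kdic,
        )
    base, delta, dist = _score_distribution(matrix, resolution)
    max_total = base + (dist.size - 1) * delta
    if score <= base + 0.5 * delta:
        return 1.0
    if score > max_total:
        return max(float(dist[-1]), math.ulp(0.0))
    k = int(math.ceil((score - base) / delta - 1e-9))
    k = min(max(k, 0), dist.size - 1)
    return float(dist[k:].sum())


# ---------------------------------------------------------------------------
# GA search


def _legal_placements(record: str, width: int) -> list[tuple[int, str]]:
    """All (offset, strand) whose window contains no masked position."""
    out = []
    for o in range(len(record) - width + 1):
        win = record[o : o + width]
        if MASK in win or "N" in win:
            continue
        out.append((o, "+"))
        out.append((o, "-"))
    return out


def _instance_word(record: str, offset: int, strand: str, width: int) -> str:
    win = record[offset : offset + width]
    return win if strand == "+" else reverse_complement(win)


def flank_background(masked: MaskedAlignment) -> np.ndarray:
    """Mononucleotide frequencies of the unmasked flank positions."""
    counts = np.zeros(4)
    for rec in masked.records:
        for ch in rec:
            if ch in LETTER_INDEX:
                counts[LETTER_INDEX[ch]] += 1
    if counts.sum() == 0:
        raise ValueError("no unmasked positions")
    bg = counts / counts.sum()
    return np.clip(bg, 1e-6, None) / np.clip(bg, 1e-6, None).sum()


def _freq_from_instances(
    words: list[str], pseudocount: float = 0.0
) -> np.ndarray:
    width = len(words[0])
    freq = np.full((4, width), pseudocount)
    for wrd in words:
        for j, c in enumerate(wrd):
            freq[LETTER_INDEX[c], j] += 1
    return freq / freq.sum(axis=0, keepdims=True)


def _build_matrix(
    masked_records: list[str],
    rec_ids: list[int],
    placements: list[tuple[int, str]],
    width: int,
    background: np.ndarray,
    motif_id: str,
) -> MotifMatrix:
    words = [
        _instance_word(masked_records[i], o, s, width)
        for i, (o, s) in zip(rec_ids, placements)
    ]
    freq = _freq_from_instances(words)
    freq_pc = _freq_from_instances(words, pseudocount=0.25)
    weights = np.log2(freq_pc / background[:, None])
    mat = MotifMatrix(
        width=width,
        freq=freq,
        weights=weights,
        background=background,
        kdic=kdic(freq, background),
        motif_id=motif_id,
    )
    mat.instances = [
        [i, o, s, mat.word_score(wrd), None, None]
        for (i, (o, s)), wrd in zip(zip(rec_ids, placements), words)
    ]
    return mat


def _greedy_polish(
    chrom: list,
    records: list[str],
    legal_lists: list[list[tuple[int, str]]],
    width: int,
    background: np.ndarray,
    max_iter: int = 50,
) -> list:
    """Deterministic hill climb after the GA: re-place every instance at
    its best-scoring position under the current matrix, while KDIC
    improves. Escapes the local optima a placement GA converges to."""
    def kd(c):
        words = [
            _instance_word(records[r], o, s, width)
            for r, (o, s) in enumerate(c)
        ]
        return kdic(_freq_from_instances(words), background)

    current = list(chrom)
    best_kdic = kd(current)
    for _ in range(max_iter):
        words = [
            _instance_word(records[r], o, s, width)
            for r, (o, s) in enumerate(current)
        ]
        freq = _freq_from_instances(words, pseudocount=0.25)
        weights = np.log2(freq / background[:, None])
        proposal = []
        for r in range(len(records)):
            best_pl, best_sc = current[r], -np.inf
            for o, s in legal_lists[r]:
                w = _instance_word(records[r], o, s, width)
                sc = sum(weights[LETTER_INDEX[c], j]
                         for j, c in enumerate(w))
                if sc > best_sc:
                    best_pl, best_sc = (o, s), sc
            proposal.append(best_pl)
        new_kdic = kd(proposal)
        if proposal != current and new_kdic > best_kdic + 1e-12:
            current, best_kdic = proposal, new_kdic
            continue
        # phase-shift moves: slide every instance by the same amount in
        # its own orientation (the usual register ambiguity of OOPS search)
        shifted_better = False
        legal_sets = [set(pl) for pl in legal_lists]
        for delta in (-2, -1, 1, 2):
            cand = []
            ok = True
            for r, (o, s) in enumerate(current):
                no = o + delta if s == "+" else o - delta
                if (no, s) not in legal_sets[r]:
                    ok = False
                    break
                cand.append((no, s))
            if not ok:
                continue
            ck = kd(cand)
            if ck > best_kdic + 1e-12:
                current, best_kdic = cand, ck
                shifted_better = True
                break
        if not shifted_better:
            break
    return current


def discover_coupling_motifs(
    masked: MaskedAlignment,
    width: int = 8,
    n_motifs: int = 3,
    ga_params: dict | None = None,
    background: np.ndarray | None = None,
    critical_p: float = 0.005,
) -> list[MotifMatrix]:
    """GA discovery of up to ``n_motifs`` coupling motifs by deflation.

    Chromosome: one (offset, strand) instance per record (OOPS model);
    fitness: KDIC of the induced frequency matrix. After each motif its
    instance windows are masked and the search repeats. Records left
    without a legal placement drop out of later rounds; discovery stops
    early if fewer than 5 records remain.
    """
    params = dict(DEFAULT_GA_PARAMS)
    if ga_params:
        params.update(ga_params)
    if "seed" not in params:
        raise ValueError("ga_params must include a seed")
    rng = np.random.default_rng(params["seed"])
    if background is None:
        background = flank_background(masked)
    background = np.asarray(background, dtype=float)

    work = list(masked.records)
    results: list[MotifMatrix] = []

    for m in range(n_motifs):
        legal = {
            i: _legal_placements(rec, width) for i, rec in enumerate(work)
        }
        rec_ids = [i for i, pl in legal.items() if pl]
        if m == 0 and len(rec_ids) < len(work):
            missing = sorted(set(legal) - set(rec_ids))
            raise ValueError(
                f"infeasible placement: records {missing} have no unmasked "
                f"window of width {width}"
            )
        if len(rec_ids) < 5:
            break
        legal_lists = [legal[i] for i in rec_ids]
        n = len(rec_ids)

        def random_chrom():
            return [
                legal_lists[r][rng.integers(len(legal_lists[r]))]
                for r in range(n)
            ]

        def fit(chrom) -> float:
            words = [
                _instance_word(work[rec_ids[r]], o, s, width)
                for r, (o, s) in enumerate(chrom)
            ]
            return kdic(_freq_from_instances(words), background)

        pop_size, gens = params["population"], params["generations"]
        mut, tour = params["mutation_rate"], params["tournament"]
        population = [random_chrom() for _ in range(pop_size)]
        fits = np.array([fit(c) for c in population])
        for _ in range(gens):
            order = np.argsort(fits)[::-1]
            new_pop = [population[order[0]]]
            while len(new_pop) < pop_size:
                parents = []
                for _ in range(2):
                    cont = rng.integers(0, pop_size, size=tour)
                    parents.append(population[cont[np.argmax(fits[cont])]])
                # uniform crossover per record
                pick = rng.random(n) < 0.5
                child = [
                    parents[0][r] if pick[r] else parents[1][r]
                    for r in range(n)
                ]
                # mutation: re-draw a record's placement
                for r in np.flatnonzero(rng.random(n) < mut):
                    child[r] = legal_lists[r][rng.integers(len(legal_lists[r]))]
                new_pop.append(child)
            population = new_pop
            fits = np.array([fit(c) for c in population])

        best = population[int(np.argmax(fits))]
        best = _greedy_polish(
            best, [work[i] for i in rec_ids], legal_lists, width, background
        )
        mat = _build_matrix(
            work, rec_ids, best, width, background, motif_id=f"motif_{m + 1}"
        )
        results.append(mat)
        # deflation: mask the found instances
        for rid, (o, s) in zip(rec_ids, best):
            rec = work[rid]
            work[rid] = rec[:o] + MASK * width + rec[o + width :]
    return results


def assign_motif_hits(
    matrix: MotifMatrix, masked: MaskedAlignment, critical_p: float
) -> tuple[list, float]:
    """Best-hit table per sequence and the critical-p score threshold.

    ``score_threshold`` is the smallest achievable score whose exact
    p-value is <= critical_p. Per sequence the best-scoring fully
    unmasked window on either strand is reported as
    [record_index, position, strand, score, p, passed].
    """
    if not 0 < critical_p <= 1:
        raise ValueError("critical_p must be in (0, 1]")
    base, delta, dist = _score_distribution(matrix)
    tails = dist[::-1].cumsum()[::-1]
    ks = np.flatnonzero(tails <= critical_p)
    if ks.size:
        score_threshold = base + ks[0] * delta
    else:
        score_threshold = base + dist.size * delta  # unreachable: none pass
    if critical_p >= 1.0:
        score_threshold = base  # everything passes

    width = matrix.width
    table = []
    for i, rec in enumerate(masked.records):
        best = None
        for o, s in _legal_placements(rec, width):
            sc = matrix.word_score(_instance_word(rec, o, s, width))
            if best is None or sc > best[2]:
                best = (o, s, sc)
        if best is None:
            table.append([i, None, None, None, None, False])
            continue
        o, s, sc = best
        p = word_score_pvalue(matrix, sc)
        passed = sc >= score_threshold - 0.5 * delta
        table.append([i, o, s, sc, p, bool(passed)])
    matrix.critical_p = critical_p
    matrix.score_threshold = float(score_threshold)
    return table, float(score_threshold)


def hits_table_tsv(table: list, masked: MaskedAlignment) -> str:
    lines = ["record\tposition\tstrand\tscore\tp_value\tpassed"]
    for row in table:
        i, o, s, sc, p, ok = row
        lines.append(
            f"{i}\t{'' if o is None else o}\t{'' if s is None else s}\t"
            f"{'' if sc is None else f'{sc:.4f}'}\t"
            f"{'' if p is None else f'{p:.3e}'}\t{int(ok)}"
        )
    return "\n".join(lines) + "\n"
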
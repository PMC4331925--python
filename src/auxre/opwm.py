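"""Optimised positional weight matrix (oPWM) recognition of AuxRE sites.

The model combines a mononucleotide and a dinucleotide log-ratio matrix
trained on a core-centred alignment of proven sites. "Optimised" refers to
the training step that searches over window locations and lengths around
the TGTCNN core and keeps the matrix geometry that best separates the
training sites from dinucleotide-shuffled decoys (area under the ROC
curve). Scores are min-max normalised to [0, 1] per matrix and the two
matrices contribute equally, so a window scoring 1.0 matches the
per-position argmax word of both matrices.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass

import numpy as np

from .sequence_core import (
    ConsensusMatcher,
    SequenceRecord,
    parse_iupac,
    reverse_complement,
    scan_consensus,
)

LETTERS = "ACGT"
LETTER_INDEX = {c: i for i, c in enumerate(LETTERS)}
DINUCS = [a + b for a in LETTERS for b in LETTERS]
DINUC_INDEX = {d: i for i, d in enumerate(DINUCS)}

CORE_PATTERN = "TGTCNN"
CORE_WIDTH = 6


@dataclass(frozen=True)
class TrainingAlignment:
    """Equal-length site sequences aligned on their TGTCNN core.

    With the default 50-nt flanks each record is 106 nt long and the core
    hexamer starts at offset 50.
    """

    records: tuple[str, ...]
    core_offset: int
    flank: int

    def __post_init__(self) -> None:
        length = 2 * self.flank + CORE_WIDTH
        matcher = parse_iupac(CORE_PATTERN)
        for i, rec in enumerate(self.records):
            if len(rec) != length:
                raise ValueError(
                    f"record {i} has length {len(rec)}, expected {length}"
                )
            core = rec[self.core_offset : self.core_offset + CORE_WIDTH]
            if not matcher.matches(core):
                raise ValueError(
                    f"record {i} core {core!r} does not match {CORE_PATTERN}"
                )

    @property
    def length(self) -> int:
        return 2 * self.flank + CORE_WIDTH

    def __len__(self) -> int:
        return len(self.records)


def build_training_alignment(
    sites: list[tuple[str, int]], flank: int = 50
) -> TrainingAlignment:
    """Align site sequences on their TGTCNN core with fixed flanks.

    Each input is ``(sequence, core_start)``; the output records are
    ``2*flank + 6`` nt long with the core at offset ``flank``, input order
    preserved.
    """
    matcher = parse_iupac(CORE_PATTERN)
    records = []
    for i, (seq, core_start) in enumerate(sites):
        seq = seq.upper()
        core = seq[core_start : core_start + CORE_WIDTH]
        if len(core) < CORE_WIDTH or not matcher.matches(core):
            raise ValueError(
                f"site {i}: window at {core_start} ({core!r}) does not match "
                f"{CORE_PATTERN}"
            )
        left = core_start
        right = len(seq) - (core_start + CORE_WIDTH)
        if left < flank or right < flank:
            raise ValueError(
                f"site {i}: needs {flank} nt flanks, has {left} left / "
                f"{right} right"
            )
        records.append(seq[core_start - flank : core_start + CORE_WIDTH + flank])
    return TrainingAlignment(tuple(records), core_offset=flank, flank=flank)


# ---------------------------------------------------------------------------
# dinucleotide-preserving shuffle (Altschul-Erickson)


def dinucleotide_shuffle(seq: str, rng: np.random.Generator) -> str:
    """Shuffle a sequence preserving its exact dinucleotide counts.

    Random Eulerian-path construction on the dinucleotide multigraph: pick
    a random last exit edge for every vertex except the terminal one such
    that the last-edge graph is a tree into the terminal vertex, shuffle
    the remaining edges, then walk.
    """
    if len(seq) < 3:
        return seq
    letters = sorted(set(seq))
    succ: dict[str, list[str]] = {c: [] for c in letters}
    for a, b in zip(seq, seq[1:]):
        succ[a].append(b)
    first, last = seq[0], seq[-1]
    # choose last edges forming a tree rooted at `last`
    vertices = [c for c in letters if succ[c]]
    while True:
        last_edge = {}
        for v in vertices:
            if v == last:
                continue
            last_edge[v] = succ[v][rng.integers(len(succ[v]))]
        # every non-terminal vertex must reach `last` via last edges
        ok = True
        for v in last_edge:
            seen = set()
            cur = v
            while cur != last:
                if cur in seen or cur not in last_edge:
                    ok = False
                    break
                seen.add(cur)
                cur = last_edge[cur]
            if not ok:
                break
        if ok:
            break
    shuffled: dict[str, list[str]] = {}
    for v in vertices:
        edges = list(succ[v])
        if v in last_edge:
            edges.remove(last_edge[v])
        rng.shuffle(edges)
        if v in last_edge:
            edges.append(last_edge[v])
        shuffled[v] = edges
    out = [first]
    cur = first
    ptr = {v: 0 for v in vertices}
    for _ in range(len(seq) - 1):
        nxt = shuffled[cur][ptr[cur]]
        ptr[cur] += 1
        out.append(nxt)
        cur = nxt
    return "".join(out)


# ---------------------------------------------------------------------------
# model


@dataclass
class PWMModel:
    """Mono+di log-ratio matrices over an optimised alignment window.

    ``window_start`` is the window's offset within the training alignment;
    ``core_in_window`` locates the TGTCNN core inside the window and is
    what anchors genome scanning. Raw scores are sums of per-position
    weights; each matrix is min-max normalised by its analytic extreme
    window scores and the final score is the mean of the two.
    """

    mono_freq: np.ndarray  # 4 x L
    di_freq: np.ndarray  # 16 x (L-1)
    mono_weights: np.ndarray
    di_weights: np.ndarray
    window_start: int
    window_length: int
    core_in_window: int
    background: np.ndarray  # 4 letter probabilities
    mono_min: float
    mono_max: float
    di_min: float
    di_max: float
    threshold: float = 0.78
    model_id: str = "oPWM"

    @property
    def window_offset(self) -> float:
        """Window center minus core center, in nt."""
        core_center = self.core_in_window + (CORE_WIDTH - 1) / 2
        return (self.window_length - 1) / 2 - core_center

    def to_json(self) -> str:
        d = {
            "model_id": self.model_id,
            "window_start": self.window_start,
            "window_length": self.window_length,
            "core_in_window": self.core_in_window,
            "background": self.background.tolist(),
            "mono_freq": self.mono_freq.tolist(),
            "di_freq": self.di_freq.tolist(),
            "mono_weights": self.mono_weights.tolist(),
            "di_weights": self.di_weights.tolist(),
            "mono_min": self.mono_min,
            "mono_max": self.mono_max,
            "di_min": self.di_min,
            "di_max": self.di_max,
            "threshold": self.threshold,
        }
        return json.dumps(d, indent=1)

    @classmethod
    def from_json(cls, text: str) -> "PWMModel":
        d = json.loads(text)
        return cls(
            mono_freq=np.asarray(d["mono_freq"]),
            di_freq=np.asarray(d["di_freq"]),
            mono_weights=np.asarray(d["mono_weights"]),
            di_weights=np.asarray(d["di_weights"]),
            window_start=d["window_start"],
            window_length=d["window_length"],
            core_in_window=d["core_in_window"],
            background=np.asarray(d["background"]),
            mono_min=d["mono_min"],
            mono_max=d["mono_max"],
            di_min=d["di_min"],
            di_max=d["di_max"],
            threshold=d["threshold"],
            model_id=d["model_id"],
        )

    def to_meme_text(self) -> str:
        """MEME-minimal-like frequency text for the mono matrix."""
        lines = [
            "MEME version 4",
            "",
            "ALPHABET= ACGT",
            "",
            f"MOTIF {self.model_id}",
            (
                f"letter-probability matrix: alength= 4 w= "
                f"{self.window_length} nsites= 0 E= 0"
            ),
        ]
        for col in self.mono_freq.T:
            lines.append(" " + " ".join(f"{v:.6f}" for v in col))
        return "\n".join(lines) + "\n"


def _count_matrices(
    records: list[str], pseudocount: float
) -> tuple[np.ndarray, np.ndarray]:
    """Column frequency tables with Laplace smoothing.

    Pseudocount is per letter; dinucleotide columns receive 4x the letter
    pseudocount spread over 16 cells so both tables add one pseudo-
    observation unit per column at the default 0.25.
    """
    length = len(records[0])
    mono = np.full((4, length), pseudocount)
    di = np.full((16, length - 1), pseudocount)
    for rec in records:
        for j, ch in enumerate(rec):
            if ch in LETTER_INDEX:
                mono[LETTER_INDEX[ch], j] += 1
        for j in range(length - 1):
            dn = rec[j : j + 2]
            if dn in DINUC_INDEX:
                di[DINUC_INDEX[dn], j] += 1
    mono /= mono.sum(axis=0, keepdims=True)
    di /= di.sum(axis=0, keepdims=True)
    return mono, di


def _weights(
    mono_freq: np.ndarray, di_freq: np.ndarray, background: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    di_bg = np.outer(background, background).reshape(16)
    mono_w = np.log2(mono_freq / background[:, None])
    di_w = np.log2(di_freq / di_bg[:, None])
    return mono_w, di_w


def _raw_scores(window: str, mono_w: np.ndarray, di_w: np.ndarray):
    m = sum(mono_w[LETTER_INDEX[c], j] for j, c in enumerate(window))
    d = sum(
        di_w[DINUC_INDEX[window[j : j + 2]], j] for j in range(len(window) - 1)
    )
    return m, d


def _build_model(
    records: list[str],
    window_start: int,
    window_length: int,
    core_offset: int,
    background: np.ndarray,
    pseudocount: float,
) -> PWMModel:
    windows = [r[window_start : window_start + window_length] for r in records]
    mono_freq, di_freq = _count_matrices(windows, pseudocount)
    mono_w, di_w = _weights(mono_freq, di_freq, background)
    return PWMModel(
        mono_freq=mono_freq,
        di_freq=di_freq,
        mono_weights=mono_w,
        di_weights=di_w,
        window_start=window_start,
        window_length=window_length,
        core_in_window=core_offset - window_start,
        background=background,
        mono_min=float(mono_w.min(axis=0).sum()),
        mono_max=float(mono_w.max(axis=0).sum()),
        di_min=float(di_w.min(axis=0).sum()),
        di_max=float(di_w.max(axis=0).sum()),
    )


def score_window_opwm(model: PWMModel, window: str) -> float:
    """Normalised [0,1] oPWM score of one window.

    Mean of the min-max-normalised mono and di raw scores. Windows
    containing ``N`` score 0.0 (masked bases are never called).
    """
    if len(window) != model.window_length:
        raise ValueError(
            f"window length {len(window)} != model window "
            f"{model.window_length}"
        )
    if "N" in window:
        return 0.0
    m, d = _raw_scores(window, model.mono_weights, model.di_weights)
    sm = (m - model.mono_min) / (model.mono_max - model.mono_min)
    sd = (d - model.di_min) / (model.di_max - model.di_min)
    return (sm + sd) / 2


def _auc(pos: np.ndarray, neg: np.ndarray) -> float:
    """Mann-Whitney AUC with tie correction."""
    from scipy.stats import rankdata

    scores = np.concatenate([pos, neg])
    ranks = rankdata(scores)
    n1, n2 = len(pos), len(neg)
    u = ranks[:n1].sum() - n1 * (n1 + 1) / 2
    return float(u / (n1 * n2))


def train_opwm(
    alignment: TrainingAlignment,
    background: np.ndarray | None = None,
    pseudocount: float = 0.25,
    candidate_offsets: range | None = None,
    candidate_lengths: range | None = None,
    n_decoys: int = 3,
    seed: int = 0,
) -> PWMModel:
    """Train the oPWM, optimising window location and length.

    Every candidate ``(window_start, length)`` whose window contains the
    6-nt core is scored by the AUC separating the training windows from
    ``n_decoys`` dinucleotide-shuffled copies of each record; ties prefer
    shorter windows, then windows centred closer to the core.
    """
    if len(alignment) < 5:
        raise ValueError("need at least 5 training records")
    if background is None:
        background = np.full(4, 0.25)
    background = np.asarray(background, dtype=float)
    if candidate_lengths is None:
        candidate_lengths = range(12, 41)

    records = list(alignment.records)
    rng = np.random.default_rng(seed)
    decoys = [
        dinucleotide_shuffle(rec, rng)
        for rec in records
        for _ in range(n_decoys)
    ]

    core_lo = alignment.core_offset
    core_hi = core_lo + CORE_WIDTH
    core_center = core_lo + (CORE_WIDTH - 1) / 2

    candidates = []
    for length in candidate_lengths:
        if length < CORE_WIDTH or length > alignment.length:
            continue
        starts = range(
            max(0, core_hi - length), min(core_lo, alignment.length - length) + 1
        )
        if candidate_offsets is not None:
            starts = [s for s in starts if s - core_lo in candidate_offsets]
        for start in starts:
            candidates.append((start, length))
    if not candidates:
        raise ValueError("empty candidate window grid")

    best = None
    for start, length in candidates:
        model = _build_model(
            records, start, length, alignment.core_offset, background, pseudocount
        )
        if model.mono_max - model.mono_min < 1e-12:
            continue  # degenerate (identical records, zero-width signal)
        pos = np.array(
            [
                score_window_opwm(model, r[start : start + length])
                for r in records
            ]
        )
        neg = np.array(
            [
                score_window_opwm(model, d[start : start + length])
                for d in decoys
            ]
        )
        auc = _auc(pos, neg)
        win_center = start + (length - 1) / 2
        key = (-auc, length, abs(win_center - core_center))
        if best is None or key < best[0]:
            best = (key, model)
    if best is None:
        # all-degenerate grid (e.g. identical records): fall back to the
        # shortest core-containing window
        start, length = candidates[0]
        return _build_model(
            records, start, length, alignment.core_offset, background, pseudocount
        )
    return best[1]


# ---------------------------------------------------------------------------
# anchored scanning / threshold calibration


def oriented_window(
    seq: str, core_start: int, strand: str, core_in_window: int, width: int
) -> str | None:
    """Extract the scoring window for a TGTCNN anchor, in site orientation.

    For a '+' anchor the window starts ``core_in_window`` nt upstream of
    the core on the plus strand. For a '-' anchor (recorded at the plus-
    strand leftmost base of the matched hexamer) the window is taken on the
    reverse complement so the core again sits at ``core_in_window``.
    Returns None when the window would run off the sequence.
    """
    if strand == "+":
        start = core_start - core_in_window
        if start < 0 or start + width > len(seq):
            return None
        return seq[start : start + width]
    length = len(seq)
    site_core_start = length - (core_start + CORE_WIDTH)
    site_start = site_core_start - core_in_window
    plus_start = length - (site_start + width)
    if site_start < 0 or plus_start < 0 or plus_start + width > length:
        return None
    return reverse_complement(seq[plus_start : plus_start + width])


def scan_opwm(
    record: SequenceRecord,
    model: PWMModel,
    threshold: float | None = None,
    anchor: ConsensusMatcher | None = None,
):
    """Anchor-based oPWM scan: score TGTCNN-anchored windows on both strands.

    Returns a list of ``(core_start, strand, score)`` for anchors whose
    window fits in the sequence and scores at or above the threshold.
    """
    from .sequence_core import SiteHit

    if threshold is None:
        threshold = model.threshold
    if anchor is None:
        anchor = parse_iupac(CORE_PATTERN)
    hits = []
    for h in scan_consensus(record, anchor, ("+", "-")):
        win = oriented_window(
            record.seq, h.start, h.strand, model.core_in_window,
            model.window_length,
        )
        if win is None:
            continue
        s = score_window_opwm(model, win)
        if s >= threshold:
            hits.append(
                SiteHit(record.id, h.start, CORE_WIDTH, h.strand, s,
                        model.model_id)
            )
    return hits


def calibrate_threshold(
    model: PWMModel,
    positive_regions: list[SequenceRecord],
    target_fraction: float,
    candidate_anchor: ConsensusMatcher | None = None,
) -> float:
    """Largest threshold keeping >= target_fraction of regions covered.

    A region is covered at threshold t when at least one TGTCNN-anchored
    window in it scores >= t. The returned threshold is the
    ceil(target * n)-th largest per-region maximum score.
    """
    if not 0 < target_fraction <= 1:
        raise ValueError("target_fraction must be in (0, 1]")
    if candidate_anchor is None:
        candidate_anchor = parse_iupac(CORE_PATTERN)
    maxima = []
    any_anchor = False
    for region in positive_regions:
        best = None
        for h in scan_consensus(region, candidate_anchor, ("+", "-")):
            any_anchor = True
            win = oriented_window(
                region.seq, h.start, h.strand, model.core_in_window,
                model.window_length,
            )
            if win is None:
                continue
            s = score_window_opwm(model, win)
            best = s if best is None else max(best, s)
        if best is not None:
            maxima.append(best)
    if not any_anchor:
        raise ValueError("no candidate anchors found in any positive region")
    n = len(positive_regions)
    k = math.ceil(target_fraction * n)
    maxima.sort(reverse=True)
    if k > len(maxima):
        warnings.warn(
            "target fraction unreachable (regions without scorable anchors); "
            "returning the smallest per-region maximum"
        )
        return maxima[-1]
    return maxima[k - 1]
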
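"""Supervised false-positive peak filtering.

MeRIP-seq peak sets carry a substantial fraction of false positives
(non-specific antibody binding, alignment artefacts, contamination).  This
module implements a two-part supervised filter:

* a mixture transition distribution (MTD) Markov model over the 200-nt peak
  sequence (alphabet A, C, G, T plus M for the called methylated adenosine).
  MTD approximates an order-L Markov chain with L lag weights and a single
  shared transition matrix, so parameters grow linearly rather than
  exponentially with the order.  Separate models are fitted to true-positive
  and false-positive training sequences; their log-likelihood ratio is a
  sequence-only discriminant.
* a random forest over peak features (the MTD likelihood ratio, distance to
  the nearest RRACH consensus, k-mer composition, enrichment/coverage/width
  peak attributes, transcript context), with optional pre-computed plug-in
  columns such as conservation or miRNA-site overlap.

Training labels come from methyltransferase-knockdown experiments: peaks
absent after knockdown are high-confidence m6A (TP); peaks whose enrichment
barely changes (<0.5-fold relative change) are technical false positives.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import joblib
import numpy as np
from sklearn.ensemble import RandomForestClassifier

from .annotation import nearest_consensus, reverse_complement
from .peakcall import PeakCall

logger = logging.getLogger(__name__)

ALPHABET = "ACGTM"
_SYM_INDEX = {c: i for i, c in enumerate(ALPHABET)}
PEAK_SEQ_LEN = 200
PEAK_SEQ_CENTER = 100

SCHEMA_VERSION = "1"


@dataclass(frozen=True)
class PeakSequence:
    """A 200-nt peak sequence over {A,C,G,T,M,N} with the site M at index 100."""

    symbols: str
    peak_id: str = ""

    def __post_init__(self) -> None:
        if len(self.symbols) != PEAK_SEQ_LEN:
            raise ValueError(f"peak sequence must be {PEAK_SEQ_LEN} nt")
        if self.symbols.count("M") != 1 or self.symbols[PEAK_SEQ_CENTER] != "M":
            raise ValueError("peak sequence must contain exactly one centred M")
        bad = set(self.symbols) - set(ALPHABET + "N")
        if bad:
            raise ValueError(f"invalid symbols {bad} in peak sequence")

    def as_indices(self) -> np.ndarray:
        """Symbol indices with N encoded as -1 (excluded from likelihoods)."""
        return np.array([_SYM_INDEX.get(c, -1) for c in self.symbols], dtype=int)


def encode_peak_sequence(peak: PeakCall, fasta, strand: str = "+") -> PeakSequence:
    """Extract the 200-nt window centred on the peak's site, marking it M.

    The site is the top deconvolved site when present, else the summit.
    Minus-strand transcripts are reverse-complemented so the model always
    reads 5'->3'.  Windows running past the contig are N-padded.
    """
    site = peak.site
    contig = fasta[peak.chrom]
    contig_len = len(contig)
    if strand == "-":
        # after reverse-complementing [lo, hi), genomic `site` lands at
        # index hi - 1 - site - lo_pad; choose hi = site + CENTER + 1
        lo = site + PEAK_SEQ_CENTER + 1 - PEAK_SEQ_LEN
        hi = site + PEAK_SEQ_CENTER + 1
    else:
        lo = site - PEAK_SEQ_CENTER
        hi = lo + PEAK_SEQ_LEN
    seq = str(contig[max(lo, 0) : min(hi, contig_len)]).upper().replace("U", "T")
    seq = "N" * max(0, -lo) + seq + "N" * max(0, hi - contig_len)
    if hi - lo != PEAK_SEQ_LEN:  # pragma: no cover - arithmetic guard
        raise AssertionError("window arithmetic error")
    if hi > contig_len or lo < 0:
        logger.warning("peak window at %s:%d runs past the contig; N-padded", peak.chrom, site)
    if strand == "-":
        seq = reverse_complement(seq)
    seq = seq[:PEAK_SEQ_CENTER] + "M" + seq[PEAK_SEQ_CENTER + 1 :]
    return PeakSequence(symbols=seq, peak_id=f"{peak.chrom}:{site}")


def label_training_peaks(
    control_peaks: list[PeakCall],
    knockdown_peaks: list[PeakCall],
    match_window: int = 50,
) -> list[tuple[PeakCall, str]]:
    """Knockdown-based training labels for control peaks.

    TP: control peak with no knockdown peak summit within ``match_window``.
    FP: matched peak whose relative enrichment change
    |enr_kd - enr_ctrl| / enr_ctrl is below 0.5.  Peaks matching with a
    larger change are ambiguous and excluded.
    """
    if not control_peaks or not knockdown_peaks:
        raise ValueError("both control and knockdown peak sets must be non-empty")
    kd_by_chrom: dict[str, list[PeakCall]] = {}
    for p in knockdown_peaks:
        kd_by_chrom.setdefault(p.chrom, []).append(p)
    labeled: list[tuple[PeakCall, str]] = []
    for peak in control_peaks:
        matches = [
            k
            for k in kd_by_chrom.get(peak.chrom, [])
            if abs(k.summit - peak.summit) <= match_window
        ]
        if not matches:
            labeled.append((peak, "TP"))
            continue
        best = min(matches, key=lambda k: abs(k.summit - peak.summit))
        if peak.enrichment <= 0:
            continue
        change = abs(best.enrichment - peak.enrichment) / peak.enrichment
        if change < 0.5:
            labeled.append((peak, "FP"))
    logger.info(
        "labeled %d/%d control peaks (%d TP, %d FP)",
        len(labeled),
        len(control_peaks),
        sum(1 for _, l in labeled if l == "TP"),
        sum(1 for _, l in labeled if l == "FP"),
    )
    return labeled


@dataclass
class MTDModel:
    """Mixture transition distribution: lag weights + one shared transition matrix."""

    order: int
    lag_weights: np.ndarray
    Q: np.ndarray
    log_likelihood: float = float("nan")
    n_iterations: int = 0

    def __post_init__(self) -> None:
        self.lag_weights = np.asarray(self.lag_weights, dtype=float)
        self.Q = np.asarray(self.Q, dtype=float)
        if self.lag_weights.shape != (self.order,):
            raise ValueError("need one weight per lag")
        if abs(self.lag_weights.sum() - 1.0) > 1e-9 or np.any(self.lag_weights < 0):
            raise ValueError("lag weights must form a simplex")
        if self.Q.shape != (len(ALPHABET), len(ALPHABET)):
            raise ValueError("Q must be |alphabet| x |alphabet|")
        if np.any(np.abs(self.Q.sum(axis=1) - 1.0) > 1e-9) or np.any(self.Q < 0):
            raise ValueError("Q rows must be stochastic")


def _transition_arrays(seqs: list[PeakSequence] | list[str], order: int):
    """Stack (previous-symbol-per-lag, current-symbol) pairs from all sequences.

    Positions involving an N (current or any lag) are skipped.
    """
    prev_rows, cur_rows = [], []
    for s in seqs:
        idx = s.as_indices() if isinstance(s, PeakSequence) else np.array(
            [_SYM_INDEX.get(c, -1) for c in s], dtype=int
        )
        n = len(idx)
        if n <= order:
            continue
        lags = np.stack([idx[order - l : n - l] for l in range(1, order + 1)], axis=1)
        cur = idx[order:]
        ok = (cur >= 0) & np.all(lags >= 0, axis=1)
        prev_rows.append(lags[ok])
        cur_rows.append(cur[ok])
    if not prev_rows:
        raise ValueError("no usable transitions in training sequences")
    return np.concatenate(prev_rows), np.concatenate(cur_rows)


def mtd_train(
    seqs: list[PeakSequence] | list[str],
    order: int = 5,
    min_sequences: int = 50,
    tol: float = 1e-6,
    max_iter: int = 300,
) -> MTDModel:
    """Fit an MTD model by EM over the lag mixture.

    P(x_t | history) = sum_l lambda_l * Q[x_{t-l}, x_t].  Initialisation is
    deterministic: uniform lag weights and Q from add-one-smoothed lag-1
    counts, so training is reproducible.  The training log-likelihood is
    non-decreasing every iteration.
    """
    if len(seqs) < min_sequences:
        raise ValueError(f"need >= {min_sequences} training sequences, got {len(seqs)}")
    for s in seqs:
        sym = s.symbols if isinstance(s, PeakSequence) else s
        bad = set(sym) - set(ALPHABET + "N")
        if bad:
            raise ValueError(f"invalid symbols {bad} in sequence {sym[:20]!r}...")
    prev, cur = _transition_arrays(seqs, order)
    m = len(ALPHABET)

    lam = np.full(order, 1.0 / order)
    counts = np.ones((m, m))
    np.add.at(counts, (prev[:, 0], cur), 1.0)
    Q = counts / counts.sum(axis=1, keepdims=True)

    prev_ll = -np.inf
    it = 0
    for it in range(1, max_iter + 1):
        comp = lam[None, :] * Q[prev, cur[:, None]]  # (n, L)
        tot = comp.sum(axis=1)
        ll = float(np.log(np.maximum(tot, 1e-300)).sum())
        resp = comp / np.maximum(tot[:, None], 1e-300)
        lam = resp.mean(axis=0)
        lam /= lam.sum()
        qcounts = np.zeros((m, m))
        for l in range(order):
            np.add.at(qcounts, (prev[:, l], cur), resp[:, l])
        qcounts += 1e-9
        Q = qcounts / qcounts.sum(axis=1, keepdims=True)
        if ll - prev_ll < tol and it > 1:
            prev_ll = ll
            break
        prev_ll = ll
    return MTDModel(order=order, lag_weights=lam, Q=Q, log_likelihood=prev_ll, n_iterations=it)


def mtd_loglik(model: MTDModel, seq: PeakSequence | str) -> float:
    """Log-likelihood of one sequence under the MTD model (N positions skipped)."""
    prev, cur = _transition_arrays([seq], model.order)
    p = (model.lag_weights[None, :] * model.Q[prev, cur[:, None]]).sum(axis=1)
    return float(np.log(np.maximum(p, 1e-300)).sum())


# --- feature schema -------------------------------------------------------

_FEATURE_CLASSES = ["CDS", "5UTR", "3UTR", "exonic", "intronic", "unknown"]
_KMERS = (
    list(ALPHABET[:4])
    + ["".join(k) for k in itertools.product("ACGT", repeat=2)]
    + ["".join(k) for k in itertools.product("ACGT", repeat=3)]
)


def feature_names(extra: tuple[str, ...] = ()) -> list[str]:
    """The versioned, ordered feature schema of the classifier."""
    base = [
        "mtd_llr",
        "consensus_distance",
        "consensus_absent",
        "enrichment",
        "ip_count",
        "region_width",
        "exon_length",
        "m_count",
    ]
    base += [f"class_{c}" for c in _FEATURE_CLASSES]
    base += [f"kmer_{k}" for k in _KMERS]
    return base + list(extra)


def extract_features(
    peak: PeakCall,
    seq: PeakSequence,
    annotation=None,
    mtd_tp: MTDModel | None = None,
    mtd_fp: MTDModel | None = None,
    extra: dict[str, float] | None = None,
) -> np.ndarray:
    """Fixed-order numeric feature vector for one peak.

    k-mer convention: for mononucleotide counts M is its own symbol (reported
    as ``m_count``; the A count excludes the M); for k=2,3 the M is mapped
    back to A (it is an adenosine) so context k-mers stay on the ACGT
    alphabet.  Missing annotation yields the ``unknown`` class; an absent
    consensus in the window sets ``consensus_absent`` and a zero distance.
    """
    if mtd_tp is None or mtd_fp is None:
        raise ValueError("both TP and FP MTD models are required")
    llr = mtd_loglik(mtd_tp, seq) - mtd_loglik(mtd_fp, seq)

    sym = seq.symbols
    plain = sym.replace("M", "A")
    dist = nearest_consensus(PEAK_SEQ_CENTER, plain, 0)
    absent = 1.0 if dist is None else 0.0
    dist_val = 0.0 if dist is None else float(dist)

    if annotation is not None:
        cls = annotation.classify_position(peak.chrom, peak.summit)
        if cls == "intergenic":
            cls = "unknown"
        tx = annotation.containing_transcript(peak.chrom, peak.summit, peak.summit + 1)
        exon_len = 0.0
        if tx is not None:
            for s, e in tx.exons:
                if s <= peak.summit < e:
                    exon_len = float(e - s)
                    break
    else:
        cls, exon_len = "unknown", 0.0

    class_onehot = [1.0 if cls == c else 0.0 for c in _FEATURE_CLASSES]
    kmer_counts = []
    for k in (1, 2, 3):
        src = sym if k == 1 else plain
        alphabet_kmers = [km for km in _KMERS if len(km) == k]
        counts = {km: 0 for km in alphabet_kmers}
        for i in range(len(src) - k + 1):
            km = src[i : i + k]
            if km in counts:
                counts[km] += 1
        kmer_counts.extend(counts[km] for km in alphabet_kmers)

    vec = [
        llr,
        dist_val,
        absent,
        float(peak.enrichment),
        float(peak.ip_count),
        float(peak.region_end - peak.region_start),
        exon_len,
        float(sym.count("M")),
        *class_onehot,
        *[float(c) for c in kmer_counts],
    ]
    if extra:
        vec.extend(float(extra[k]) for k in sorted(extra))
    return np.array(vec, dtype=float)


# --- random forest --------------------------------------------------------


@dataclass
class PeakClassifier:
    """Random-forest ensemble over the documented feature schema."""

    forest: RandomForestClassifier
    feature_schema: list[str]
    schema_version: str = SCHEMA_VERSION
    oob_error: float = float("nan")
    mtd_tp: "MTDModel | None" = None
    mtd_fp: "MTDModel | None" = None

    def vote_fraction(self, X: np.ndarray) -> np.ndarray:
        """Fraction of trees voting TP (class 1) for each row."""
        X = np.asarray(X, dtype=float)
        votes = np.zeros(len(X))
        for tree in self.forest.estimators_:
            votes += tree.predict(X)
        return votes / len(self.forest.estimators_)

    def save(self, path: str) -> None:
        joblib.dump(self, path)

    @staticmethod
    def load(path: str) -> "PeakClassifier":
        model = joblib.load(path)
        if model.schema_version != SCHEMA_VERSION:  # pragma: no cover
            raise ValueError(
                f"model schema version {model.schema_version} != {SCHEMA_VERSION}"
            )
        return model


def train_classifier(
    features: np.ndarray,
    labels: list[str] | np.ndarray,
    n_trees: int = 1000,
    mtry: int = 6,
    seed: int = 0,
    feature_schema: list[str] | None = None,
) -> PeakClassifier:
    """Train the bagged random-decision-tree ensemble (majority vote).

    ``mtry`` features are considered at each split; the out-of-bag error is
    reported.  Reproducible under a fixed seed.
    """
    X = np.asarray(features, dtype=float)
    y = np.array([1 if l == "TP" else 0 for l in labels], dtype=int)
    if len(set(y.tolist())) < 2:
        raise ValueError("training data must contain both TP and FP examples")
    forest = RandomForestClassifier(
        n_estimators=n_trees,
        max_features=min(mtry, X.shape[1]),
        oob_score=True,
        random_state=seed,
        n_jobs=1,
    )
    forest.fit(X, y)
    oob = 1.0 - forest.oob_score_
    logger.info("random forest trained: %d trees, OOB error %.4f", n_trees, oob)
    schema = feature_schema or feature_names()
    if len(schema) != X.shape[1]:
        raise ValueError(
            f"feature schema has {len(schema)} names but data has {X.shape[1]} columns"
        )
    return PeakClassifier(forest=forest, feature_schema=schema, oob_error=oob)


@dataclass(frozen=True)
class ClassifierScore:
    score: float
    label: str

    def __post_init__(self) -> None:
        if not (0.0 <= self.score <= 1.0):
            raise ValueError("score must be in [0, 1]")


def score_peaks(
    model: PeakClassifier,
    peaks: list[PeakCall],
    features: np.ndarray,
    threshold: float = 0.5,
    feature_schema: list[str] | None = None,
) -> list[ClassifierScore]:
    """Score peaks with the trained ensemble and flag likely false positives.

    Scores are tree-vote fractions (0-0.5 likely false positive, 0.5-1 likely
    genuine m6A at the default threshold); the threshold biases the filter
    toward precision (higher) or recall (lower).  FP-labeled peaks get the
    ``fp_filtered`` flag but are retained in the full output.
    """
    schema = feature_schema or feature_names()
    if schema != model.feature_schema:
        ours, theirs = set(schema), set(model.feature_schema)
        raise ValueError(
            "feature schema mismatch vs training; "
            f"missing={sorted(theirs - ours)} unexpected={sorted(ours - theirs)}"
        )
    scores = model.vote_fraction(np.asarray(features, dtype=float))
    out: list[ClassifierScore] = []
    for peak, s in zip(peaks, scores):
        label = "TP" if s >= threshold else "FP"
        peak.fp_score = float(s)
        if label == "FP":
            peak.flags.add("fp_filtered")
        out.append(ClassifierScore(score=float(s), label=label))
    return out
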
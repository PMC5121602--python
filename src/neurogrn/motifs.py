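"""PWM scanning and hypergeometric motif enrichment in target vs background
sequence sets.

A position weight matrix is scanned over both strands of each sequence with
log-odds scores sum_i log2(p_i(base) / bg(base)); a position is a hit when its
score reaches ``score_fraction`` (default 0.8) of the maximum attainable
log-odds. Enrichment of a motif among target sequences is the hypergeometric
upper tail over sequence-level occurrence: population = targets + backgrounds,
successes = sequences with >= 1 hit, draws = targets. q-values are
Benjamini-Hochberg across the motif library.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
from Bio import motifs as bio_motifs
from pyfaidx import Fasta
from scipy import stats

from .intervals import ChromSizes, GenomicInterval, IntervalSet

__all__ = [
    "DEFAULT_SCORE_FRACTION",
    "PWM_PSEUDOCOUNT",
    "MotifPWM",
    "MotifHit",
    "MotifEnrichmentResult",
    "read_jaspar",
    "scan_pwm",
    "sequence_has_hit",
    "motif_enrichment_test",
    "rank_motifs",
    "extract_peak_sequences",
    "sample_background_regions",
]

DEFAULT_SCORE_FRACTION = 0.8
PWM_PSEUDOCOUNT = 0.01

_BASES = "ACGT"
_BASE_INDEX = {b: i for i, b in enumerate(_BASES)}
_COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}


@dataclass
class MotifPWM:
    """A 4 x L base-probability matrix (rows A, C, G, T) with background.

    Columns are renormalized to sum to 1 after adding ``pseudocount``.
    """

    name: str
    matrix: np.ndarray
    pseudocount: float = PWM_PSEUDOCOUNT
    background: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.shape[0] != 4 or self.matrix.shape[1] < 1:
            raise ValueError("PWM matrix must be 4 x L with L >= 1")
        m = self.matrix + self.pseudocount
        self.matrix = m / m.sum(axis=0, keepdims=True)
        if self.background is None:
            self.background = np.full(4, 0.25)
        self.background = np.asarray(self.background, dtype=float)

    @property
    def length(self) -> int:
        return self.matrix.shape[1]

    def log_odds(self) -> np.ndarray:
        """4 x L log2(p / bg) matrix; zero probabilities give -inf."""
        with np.errstate(divide="ignore"):
            return np.log2(self.matrix / self.background[:, None])

    def max_score(self) -> float:
        return float(self.log_odds().max(axis=0).sum())

    def consensus(self) -> str:
        return "".join(_BASES[i] for i in self.matrix.argmax(axis=0))

    def shuffled(self, rng: np.random.Generator) -> "MotifPWM":
        """Column-shuffled control PWM (same composition, scrambled order)."""
        perm = rng.permutation(self.length)
        return MotifPWM(
            name=f"{self.name}_shuffled", matrix=self.matrix[:, perm],
            pseudocount=0.0, background=self.background,
        )


@dataclass
class MotifHit:
    sequence_id: str
    offset: int  # 0-based on the forward strand
    strand: str
    log_odds_score: float


@dataclass
class MotifEnrichmentResult:
    motif_name: str
    n_target_with: int
    n_target: int
    n_background_with: int
    n_background: int
    p_value: float
    q_value: float | None = None


def read_jaspar(path: str | Path) -> list[MotifPWM]:
    """Read a JASPAR plain-text matrix file into count-normalized PWMs."""
    out = []
    with open(path) as fh:
        for m in bio_motifs.parse(fh, "jaspar"):
            counts = np.array([m.counts[b] for b in _BASES], dtype=float)
            out.append(MotifPWM(name=m.matrix_id or m.name, matrix=counts / counts.sum(axis=0)))
    return out


def write_jaspar(pwms: list[MotifPWM], path: str | Path) -> None:
    """Write PWMs (scaled to integer-ish counts of 100) in JASPAR format."""
    with open(path, "w") as fh:
        for pwm in pwms:
            fh.write(f">{pwm.name}\t{pwm.name}\n")
            counts = np.round(pwm.matrix * 100, 4)
            for i, base in enumerate(_BASES):
                vals = " ".join(format(v, "g") for v in counts[i])
                fh.write(f"{base}  [ {vals} ]\n")


def _encode(seq: str) -> np.ndarray:
    """Sequence -> integer codes; N (or any non-ACGT) -> 4."""
    arr = np.frombuffer(seq.upper().encode("ascii"), dtype=np.uint8)
    codes = np.full(arr.shape, 4, dtype=np.int8)
    for base, idx in _BASE_INDEX.items():
        codes[arr == ord(base)] = idx
    return codes


def _window_scores(codes: np.ndarray, lo: np.ndarray) -> np.ndarray:
    """Log-odds score at every offset; N contributes 0."""
    L = lo.shape[1]
    n_off = len(codes) - L + 1
    lo5 = np.vstack([lo, np.zeros(L)])  # row 4: N scores 0
    scores = np.zeros(n_off)
    for j in range(L):
        scores += lo5[codes[j : j + n_off], j]
    return scores


def _revcomp(seq: str) -> str:
    return "".join(_COMPLEMENT.get(b, "N") for b in reversed(seq.upper()))


def scan_pwm(
    sequences: dict[str, str],
    pwm: MotifPWM,
    score_fraction: float = DEFAULT_SCORE_FRACTION,
) -> list[MotifHit]:
    """All positions on both strands scoring >= score_fraction * max score.

    Reverse-strand hits are reported at their forward-strand offset. Sequences
    shorter than the motif are skipped (empty result if all are).
    """
    if not 0 < score_fraction <= 1:
        raise ValueError("score_fraction must be in (0, 1]")
    lo = pwm.log_odds()
    threshold = score_fraction * pwm.max_score()
    L = pwm.length
    hits = []
    for seq_id, seq in sequences.items():
        if len(seq) < L:
            continue
        fwd = _encode(seq)
        rev = _encode(_revcomp(seq))
        n_off = len(seq) - L + 1
        for strand, codes in (("+", fwd), ("-", rev)):
            scores = _window_scores(codes, lo)
            for off in np.nonzero(scores >= threshold - 1e-12)[0]:
                offset = int(off) if strand == "+" else n_off - 1 - int(off)
                hits.append(
                    MotifHit(
                        sequence_id=seq_id, offset=offset, strand=strand,
                        log_odds_score=float(scores[off]),
                    )
                )
    return hits


def sequence_has_hit(
    sequences: dict[str, str], pwm: MotifPWM, score_fraction: float = DEFAULT_SCORE_FRACTION
) -> dict[str, bool]:
    """Sequence-level zero/one motif occurrence."""
    with_hit = {h.sequence_id for h in scan_pwm(sequences, pwm, score_fraction)}
    return {sid: sid in with_hit for sid in sequences}


def motif_enrichment_test(
    targets: dict[str, str],
    backgrounds: dict[str, str],
    pwm: MotifPWM,
    score_fraction: float = DEFAULT_SCORE_FRACTION,
) -> MotifEnrichmentResult:
    """Hypergeometric upper-tail enrichment of motif-bearing target sequences.

    P(X >= k) with population N = |targets| + |backgrounds|, successes
    K = sequences with the motif anywhere, draws n = |targets|, observed
    k = targets with the motif.
    """
    if not targets or not backgrounds:
        raise ValueError("both sequence sets must be non-empty")
    shared = set(targets) & set(backgrounds)
    if shared:
        raise ValueError(f"sequence ids present in both sets: {sorted(shared)[:5]}")
    t_hit = sequence_has_hit(targets, pwm, score_fraction)
    b_hit = sequence_has_hit(backgrounds, pwm, score_fraction)
    k = sum(t_hit.values())
    K = k + sum(b_hit.values())
    n = len(targets)
    N = len(targets) + len(backgrounds)
    p = float(stats.hypergeom.sf(k - 1, N, K, n))
    return MotifEnrichmentResult(
        motif_name=pwm.name, n_target_with=k, n_target=n,
        n_background_with=K - k, n_background=len(backgrounds), p_value=p,
    )


def rank_motifs(
    targets: dict[str, str],
    backgrounds: dict[str, str],
    pwm_library: list[MotifPWM],
    score_fraction: float = DEFAULT_SCORE_FRACTION,
) -> list[MotifEnrichmentResult]:
    """Enrichment per PWM with BH q-values, sorted ascending by p-value."""
    if not pwm_library:
        raise ValueError("empty PWM library")
    results = [
        motif_enrichment_test(targets, backgrounds, pwm, score_fraction)
        for pwm in pwm_library
    ]
    p = np.array([r.p_value for r in results])
    q = stats.false_discovery_control(p, method="bh")
    for r, qi in zip(results, q):
        r.q_value = float(qi)
    results.sort(key=lambda r: (r.p_value, r.motif_name))
    return results


def extract_peak_sequences(peaks: IntervalSet, genome_fasta: str | Path) -> dict[str, str]:
    """One upper-cased sequence per peak, keyed by peak name.

    Peaks extending past their chromosome end raise an error naming the peak.
    """
    fasta = Fasta(str(genome_fasta))
    out: dict[str, str] = {}
    for i, iv in enumerate(peaks):
        if iv.chrom not in fasta:
            raise ValueError(f"peak {iv.name}: chromosome {iv.chrom} not in FASTA")
        if iv.end > len(fasta[iv.chrom]):
            raise ValueError(
                f"peak {iv.name} ({iv.chrom}:{iv.start}-{iv.end}) exceeds sequence length"
            )
        key = iv.name if iv.name not in (".", "") else f"peak_{i}"
        out[key] = str(fasta[iv.chrom][iv.start : iv.end]).upper()
    return out


def sample_background_regions(
    peaks: IntervalSet,
    chrom_sizes: ChromSizes,
    seed: int,
    n_per_peak: int = 2,
    max_tries: int = 1000,
) -> IntervalSet:
    """Length-matched background intervals avoiding all peak positions.

    For each peak, ``n_per_peak`` regions of identical length are placed
    uniformly on a random chromosome, rejecting placements overlapping any
    peak; deterministic per seed.
    """
    rng = np.random.default_rng(seed)
    peak_trees = peaks.trees()
    chroms = list(chrom_sizes.sizes)
    out = []
    for i, iv in enumerate(peaks):
        length = len(iv)
        for j in range(n_per_peak):
            for _ in range(max_tries):
                chrom = chroms[rng.integers(len(chroms))]
                limit = chrom_sizes[chrom] - length
                if limit < 0:
                    continue
                start = int(rng.integers(limit + 1))
                tree = peak_trees.get(chrom)
                if tree is not None and tree.overlaps(start, start + length):
                    continue
                out.append(
                    GenomicInterval(chrom, start, start + length, name=f"bg_{i}_{j}")
                )
                break
            else:
                raise RuntimeError(
                    f"could not place background region for peak {iv.name} "
                    f"after {max_tries} tries"
                )
    return IntervalSet(out).normalize()
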
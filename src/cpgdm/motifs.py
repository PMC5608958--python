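"""PWM and k-mer enrichment in fixed-width windows around CpG sites."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .stats import EnrichmentResult, bh_adjust, fisher_exact_2x2, finalize_q, odds_ratio_woolf

__all__ = [
    "PWM",
    "SequenceWindow",
    "extract_windows",
    "pwm_window_enrichment",
    "kmer_enrichment",
    "revcomp",
    "canonical_kmer",
    "decoy_pwms",
]

_ALPHABET = "ACGT"
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")
_CODE = {b: i for i, b in enumerate(_ALPHABET)}

UNIFORM_BG = np.full(4, 0.25)


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def canonical_kmer(kmer: str) -> str:
    rc = revcomp(kmer)
    return min(kmer, rc)


@dataclass
class PWM:
    """Position probability matrix over A, C, G, T with a background model."""

    name: str
    matrix: np.ndarray  # (length, 4), rows sum to 1
    background: np.ndarray = field(default_factory=lambda: UNIFORM_BG.copy())
    pseudocount: float = 0.0

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        self.background = np.asarray(self.background, dtype=float)
        if self.matrix.ndim != 2 or self.matrix.shape[1] != 4:
            raise ValueError("PWM matrix must be (length, 4)")
        if self.pseudocount:
            self.matrix = self.matrix + self.pseudocount
            self.matrix = self.matrix / self.matrix.sum(axis=1, keepdims=True)
        if not np.allclose(self.matrix.sum(axis=1), 1.0, atol=1e-9):
            raise ValueError("PWM columns must each sum to 1")
        if not np.isclose(self.background.sum(), 1.0, atol=1e-9):
            raise ValueError("background must sum to 1")

    def __len__(self) -> int:
        return self.matrix.shape[0]

    def log_odds(self) -> np.ndarray:
        with np.errstate(divide="ignore"):
            return np.log2(np.maximum(self.matrix, 1e-300) / self.background)

    def max_score(self) -> float:
        return float(self.log_odds().max(axis=1).sum())

    def consensus(self) -> str:
        return "".join(_ALPHABET[i] for i in self.matrix.argmax(axis=1))

    @classmethod
    def from_consensus(cls, name: str, consensus: str, certainty: float = 0.997,
                       background=None) -> "PWM":
        from .simulate import IUPAC

        L = len(consensus)
        mat = np.zeros((L, 4))
        for i, ch in enumerate(consensus.upper()):
            allowed = [_CODE[b] for b in IUPAC[ch]]
            mat[i, :] = (1 - certainty) / (4 - len(allowed)) if len(allowed) < 4 else 0.25
            for a in allowed:
                mat[i, a] = certainty / len(allowed) if len(allowed) < 4 else 0.25
        bg = UNIFORM_BG.copy() if background is None else np.asarray(background, float)
        return cls(name=name, matrix=mat, background=bg)


def decoy_pwms(n: int, length: int = 7, seed: int = 0, avoid: str | None = None) -> list[PWM]:
    """Random sharp consensus PWMs used as negative controls in ranking tests."""
    rng = np.random.default_rng(seed)
    out = []
    avoid_set = {avoid, revcomp(avoid)} if avoid else set()
    while len(out) < n:
        cons = "".join(_ALPHABET[i] for i in rng.integers(0, 4, size=length))
        if cons in avoid_set:
            continue
        out.append(PWM.from_consensus(f"decoy_{len(out):02d}", cons))
    return out


@dataclass
class SequenceWindow:
    site_id: str
    chrom: str
    start: int
    end: int
    sequence: str
    cpg_offset: int
    padded: bool = False

    def __post_init__(self) -> None:
        if len(self.sequence) != self.end - self.start:
            raise ValueError("sequence length does not match window span")
        bad = set(self.sequence) - set("ACGTN")
        if bad:
            raise ValueError(f"invalid bases in window: {sorted(bad)}")


def extract_windows(
    sites: pd.DataFrame, genome: dict[str, np.ndarray], width: int = 40
) -> list[SequenceWindow]:
    """Width-bp windows centred on each site's CpG anchor (offset width/2).

    Windows truncated at chromosome ends are N-padded and flagged.
    """
    if width <= 0 or width % 2:
        raise ValueError("width must be a positive even number")
    half = width // 2
    out = []
    for chrom, pos in zip(sites["chrom"], sites["pos"]):
        seq_arr = genome.get(chrom)
        if seq_arr is None:
            raise KeyError(f"chromosome {chrom!r} not in genome")
        size = seq_arr.size
        pos = int(pos)
        if not 0 <= pos < size:
            raise ValueError(f"site {chrom}:{pos} beyond chromosome end ({size})")
        lo, hi = pos - half, pos + half
        left_pad = max(0, -lo)
        right_pad = max(0, hi - size)
        core = "".join(seq_arr[max(0, lo) : min(hi, size)]).upper()
        seq = "N" * left_pad + core + "N" * right_pad
        out.append(
            SequenceWindow(
                site_id=f"{chrom}:{pos}",
                chrom=chrom,
                start=lo,
                end=hi,
                sequence=seq,
                cpg_offset=half,
                padded=bool(left_pad or right_pad),
            )
        )
    return out


def _encode(seq: str) -> np.ndarray:
    """A,C,G,T -> 0..3; anything else (N) -> 4."""
    arr = np.frombuffer(seq.encode(), dtype=np.uint8)
    out = np.full(arr.size, 4, dtype=np.int8)
    for b, i in _CODE.items():
        out[arr == ord(b)] = i
    return out


def best_pwm_score(window_seq: str, pwm: PWM) -> float:
    """Max log2-odds over both strands and all offsets; N scores 0."""
    L = len(pwm)
    if len(window_seq) < L:
        return -np.inf
    lods = np.hstack([pwm.log_odds(), np.zeros((L, 1))])  # column 4 = N -> 0
    best = -np.inf
    for seq in (window_seq, revcomp(window_seq)):
        codes = _encode(seq)
        idx = np.lib.stride_tricks.sliding_window_view(codes, L)
        scores = lods[np.arange(L)[None, :], idx].sum(axis=1)
        if scores.size:
            best = max(best, float(scores.max()))
    return best


def pwm_window_enrichment(
    dm_windows: list[SequenceWindow],
    bg_windows: list[SequenceWindow],
    pwms: list[PWM],
    score_fraction: float = 0.8,
) -> list[EnrichmentResult]:
    """Per-PWM Fisher enrichment of hit-bearing windows, ranked by (q, -OR).

    A window is a hit when its best log2-odds score on either strand reaches
    ``score_fraction`` of the PWM's maximum attainable score.
    """
    if not dm_windows or not bg_windows:
        raise ValueError("both window sets must be non-empty")
    if not 0 < score_fraction <= 1:
        raise ValueError("score_fraction must lie in (0, 1]")
    results = []
    for pwm in pwms:
        threshold = score_fraction * pwm.max_score()
        a = sum(best_pwm_score(w.sequence, pwm) >= threshold for w in dm_windows)
        c = sum(best_pwm_score(w.sequence, pwm) >= threshold for w in bg_windows)
        results.append(
            EnrichmentResult(
                label=pwm.name,
                a=int(a),
                b=len(dm_windows) - int(a),
                c=int(c),
                d=len(bg_windows) - int(c),
            )
        )
    finalize_q(results)
    results.sort(key=lambda r: (r.q, -r.odds_ratio, r.label))
    return results


def _window_kmers(seq: str, k: int) -> set[str]:
    return {
        canonical_kmer(seq[i : i + k])
        for i in range(len(seq) - k + 1)
        if "N" not in seq[i : i + k]
    }


def kmer_enrichment(
    dm_windows: list[SequenceWindow],
    bg_windows: list[SequenceWindow],
    k_range=(6, 7, 8),
    top_n: int | None = None,
) -> pd.DataFrame:
    """Canonical k-mer over-representation (presence per window), BH within k.

    Ranked by (k, q, -OR, kmer). Presence semantics: a k-mer counts once per
    window regardless of occurrence count.
    """
    if not dm_windows or not bg_windows:
        raise ValueError("both window sets must be non-empty")
    width = len(dm_windows[0].sequence)
    rows = []
    for k in k_range:
        if k > width:
            raise ValueError(f"k={k} exceeds window width {width}")
        dm_counts: dict[str, int] = {}
        bg_counts: dict[str, int] = {}
        for windows, counts in ((dm_windows, dm_counts), (bg_windows, bg_counts)):
            for w in windows:
                for km in _window_kmers(w.sequence, k):
                    counts[km] = counts.get(km, 0) + 1
        kmers = sorted(set(dm_counts) | set(bg_counts))
        n_dm, n_bg = len(dm_windows), len(bg_windows)
        ps, ors = [], []
        for km in kmers:
            a = dm_counts.get(km, 0)
            c = bg_counts.get(km, 0)
            ps.append(fisher_exact_2x2(a, n_dm - a, c, n_bg - c))
            ors.append(odds_ratio_woolf(a, n_dm - a, c, n_bg - c)[0])
        qs = bh_adjust(ps) if kmers else []
        for km, p, q, o in zip(kmers, ps, qs, ors):
            rows.append(
                {
                    "k": k,
                    "kmer": km,
                    "dm_windows": dm_counts.get(km, 0),
                    "bg_windows": bg_counts.get(km, 0),
                    "odds_ratio": o,
                    "p": p,
                    "q": q,
                }
            )
    out = pd.DataFrame(rows, columns=["k", "kmer", "dm_windows", "bg_windows",
                                      "odds_ratio", "p", "q"])
    out = out.sort_values(
        ["k", "q", "odds_ratio", "kmer"], ascending=[True, True, False, True],
        kind="stable",
    ).reset_index(drop=True)
    if top_n is not None:
        out = out.groupby("k", group_keys=False).head(top_n).reset_index(drop=True)
    return out
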
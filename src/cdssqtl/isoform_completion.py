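"""Long-read candidate-isoform completion filters: reference TSS/TES end
proximity, longest-ORF extraction, coding-probability thresholding,
CDSI-junction matching, TSS-usage contingency testing, and per-gene
completion summaries.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from Bio.Seq import Seq
from scipy import stats

logger = logging.getLogger(__name__)

CODING_PROB_MIN = 0.364  # printed human cutoff of the coding-potential tool
END_PROXIMITY_BP = 50

_START = re.compile("ATG")
_STOPS = {"TAA", "TAG", "TGA"}


@dataclass
class CandidateIsoform:
    candidate_id: str
    chrom: str
    strand: str
    five_prime_end: int
    three_prime_end: int
    introns: list[tuple[int, int]] = field(default_factory=list)
    spliced_sequence: str | None = None
    coding_probability: float | None = None
    read_count: int = 0
    gene_id: str = ""

    def __post_init__(self) -> None:
        self.introns = sorted(self.introns)


@dataclass
class OrfCall:
    start_offset: int  # 0-based half-open, on the spliced sequence
    end_offset: int
    protein: str
    length_nt: int
    has_ambiguous: bool = False


def _interval_distance(pos: int, start: int, end: int) -> int:
    """Distance in bp from a 1-based position to a 1-based inclusive
    interval; 0 if inside."""
    if pos < start:
        return start - pos
    if pos > end:
        return pos - end
    return 0


def read_bed_intervals(path) -> pd.DataFrame:
    """BED (0-based half-open) -> 1-based inclusive intervals."""
    df = pd.read_csv(path, sep="\t", header=None, comment="#",
                     usecols=[0, 1, 2], names=["chrom", "start", "end"])
    df["start"] = df["start"] + 1
    return df


def min_distance_to_set(chrom: str, pos: int, ref: pd.DataFrame) -> float:
    sub = ref[ref["chrom"] == chrom]
    if sub.empty:
        return np.inf
    d = np.minimum(
        np.abs(sub["start"].to_numpy() - pos),
        np.abs(sub["end"].to_numpy() - pos),
    )
    inside = (sub["start"].to_numpy() <= pos) & (pos <= sub["end"].to_numpy())
    d[inside] = 0
    return float(d.min())


def end_proximity_filter(
    candidates: list[CandidateIsoform],
    tss_ref: pd.DataFrame,
    tes_ref: pd.DataFrame,
    max_dist: int = END_PROXIMITY_BP,
) -> pd.DataFrame:
    """Flag candidates whose 5' end lies within ``max_dist`` bp (inclusive)
    of a reference TSS interval AND whose 3' end lies within ``max_dist`` of
    a reference TES interval. Distance is measured to the nearest interval
    edge and is 0 inside an interval."""
    if tss_ref.empty or tes_ref.empty:
        logger.warning("empty TSS/TES reference set: every candidate fails")
    rows = []
    for c in candidates:
        d5 = min_distance_to_set(c.chrom, c.five_prime_end, tss_ref)
        d3 = min_distance_to_set(c.chrom, c.three_prime_end, tes_ref)
        rows.append({
            "candidate_id": c.candidate_id,
            "tss_distance": d5,
            "tes_distance": d3,
            "tss_ok": d5 <= max_dist,
            "tes_ok": d3 <= max_dist,
            "passed": (d5 <= max_dist) and (d3 <= max_dist),
        })
    return pd.DataFrame(rows)


def longest_orf(spliced_sequence: str) -> OrfCall | None:
    """Longest complete ORF (ATG..stop) over the three forward frames.

    Ties go to the 5'-most start. Codons containing N translate to X and the
    call is flagged. Returns None when no complete ORF exists.
    """
    seq = spliced_sequence.upper()
    best: OrfCall | None = None
    for m in _START.finditer(seq):
        s = m.start()
        for e in range(s + 3, len(seq) - 2, 3):
            codon = seq[e:e + 3]
            if codon in _STOPS:
                length = e + 3 - s
                if best is None or length > best.length_nt:
                    orf = seq[s:e + 3]
                    has_n = "N" in orf
                    protein = str(Seq(orf[:-3]).translate())
                    if has_n:
                        logger.info("ORF at %d contains N; ambiguous codons -> X", s)
                    best = OrfCall(s, e + 3, protein, length, has_n)
                break
    return best


def coding_filter(
    candidates: list[CandidateIsoform], min_prob: float = CODING_PROB_MIN
) -> tuple[list[CandidateIsoform], list[CandidateIsoform], list[CandidateIsoform]]:
    """Split candidates into (passed, failed, unscored) on coding
    probability >= ``min_prob`` (inclusive). Candidates without a score land
    in the unscored bucket rather than being dropped."""
    passed, failed, unscored = [], [], []
    for c in candidates:
        if c.coding_probability is None:
            unscored.append(c)
        elif c.coding_probability >= min_prob:
            passed.append(c)
        else:
            failed.append(c)
    return passed, failed, unscored


def junction_match(
    candidate: CandidateIsoform, target_junction: tuple[int, int]
) -> bool:
    """True iff the exact (donor, acceptor) pair occurs in the candidate's
    intron chain (1-based intron boundary coordinates)."""
    return tuple(target_junction) in {tuple(j) for j in candidate.introns}


def tss_usage_test(counts) -> tuple[float, float]:
    """Pearson chi-squared (no continuity correction) on a 2x2 table of
    TSS class x splice-acceptor class; 1 df, two-sided p."""
    tab = np.asarray(counts, dtype=float)
    if tab.shape != (2, 2):
        raise ValueError("expected a 2x2 table")
    if (tab < 0).any():
        raise ValueError("negative cell count")
    if tab.sum() == 0 or (tab.sum(axis=0) == 0).any() or (tab.sum(axis=1) == 0).any():
        raise ValueError("zero marginal: chi-squared test undefined")
    chi2, p, _, _ = stats.chi2_contingency(tab, correction=False)
    return float(chi2), float(p)


def summarize_completion(
    candidates: list[CandidateIsoform],
    passed_ids: set,
    min_share: float = 0.5,
) -> pd.DataFrame:
    """Per-gene report over passing candidates: count, total reads, and the
    smallest read-count-descending prefix covering >= ``min_share`` of the
    gene's completed reads (ties broken by candidate id)."""
    by_gene: dict[str, list[CandidateIsoform]] = {}
    for c in candidates:
        if c.candidate_id in passed_ids:
            by_gene.setdefault(c.gene_id, []).append(c)
    rows = []
    for gene_id in sorted(by_gene):
        cs = sorted(by_gene[gene_id],
                    key=lambda c: (-c.read_count, c.candidate_id))
        total = sum(c.read_count for c in cs)
        if total == 0:
            logger.warning("gene %s: zero total reads; share undefined", gene_id)
            rows.append({"gene_id": gene_id, "n_passing": len(cs),
                         "total_reads": 0, "n_majority": np.nan})
            continue
        acc = 0
        n_majority = 0
        for c in cs:
            acc += c.read_count
            n_majority += 1
            if acc / total >= min_share:
                break
        rows.append({"gene_id": gene_id, "n_passing": len(cs),
                     "total_reads": total, "n_majority": n_majority})
    return pd.DataFrame(rows)
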
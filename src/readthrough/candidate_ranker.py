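"""Combine readthrough propensity and PTS1 probability into a product score.

Candidates for functional readthrough with a hidden peroxisomal signal
combine a high RTP (a readthrough-prone stop-codon context) with a high
probability that the readthrough extension ends in a PTS1.  RTP scores
are min-max normalized over the scored cohort to RTP⁺ in [0,1] and
multiplied by the PTS1 probability; transcripts with an unbounded
extension (no second in-frame stop) carry no product score and sort last.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

from readthrough import core_seq, pts1_model, rtp_model
from readthrough.core_seq import Transcript, extract_scc, find_extension, translate


@dataclass(frozen=True)
class CandidateScore:
    transcript_id: str
    rtp: float
    rtp_plus: float
    pts1_prob: Optional[float]
    product: Optional[float]
    consensus_match: bool


def _parent_cterm(t: Transcript, max_residues: int = 11) -> str:
    """Translate the in-frame coding region immediately upstream of the stop."""
    n_codons = min(max_residues, (t.stop_start - 1) // 3)
    start = t.stop_start - 1 - 3 * n_codons
    region = t.seq[start : t.stop_start - 1]
    try:
        return translate(region)
    except ValueError:
        return ""


def matches_consensus(t: Transcript, motif: str) -> bool:
    """Exact match of the motif anchored at the stop codon (+1 onward)."""
    region = t.seq[t.stop_start - 1 : t.stop_start - 1 + len(motif)]
    return region == motif


def rank(
    transcripts: Sequence[Transcript],
    rtp: Optional[rtp_model.RTPModel] = None,
    pts1: Optional[pts1_model.PTS1Model] = None,
    consensus_motif: Optional[str] = None,
) -> list[CandidateScore]:
    """Rank transcripts by RTP⁺ × PTS1 product score (descending).

    Transcripts without a bounded extension keep their RTP but have no
    PTS1 probability or product and sort below every scored transcript;
    remaining ties break by RTP (descending) then id.  Requires a cohort
    of at least 2 for the min-max normalization; a degenerate cohort where
    every RTP is identical sets RTP⁺=1 for all with a warning.
    """
    if len(transcripts) < 2:
        raise ValueError("ranking requires a cohort of at least 2 transcripts")
    rtp = rtp or rtp_model.default_model()
    pts1 = pts1 or pts1_model.default_model()
    if consensus_motif is None:
        consensus_motif = rtp_model.consensus(rtp).motif

    rtp_scores = {t.id: rtp_model.score(rtp, extract_scc(t)) for t in transcripts}
    lo, hi = min(rtp_scores.values()), max(rtp_scores.values())
    if hi == lo:
        warnings.warn("all transcripts share one RTP value; RTP+ set to 1.0", stacklevel=2)

    results = []
    for t in transcripts:
        r = rtp_scores[t.id]
        r_plus = 1.0 if hi == lo else (r - lo) / (hi - lo)
        ext = find_extension(t)
        if ext.bounded:
            prob = pts1_model.score_extension(pts1, ext, parent_cterm=_parent_cterm(t)).probability
            product = r_plus * prob
        else:
            prob = None
            product = None
        results.append(
            CandidateScore(
                transcript_id=t.id,
                rtp=r,
                rtp_plus=r_plus,
                pts1_prob=prob,
                product=product,
                consensus_match=matches_consensus(t, consensus_motif),
            )
        )
    results.sort(
        key=lambda c: (
            c.product is None,
            -(c.product if c.product is not None else 0.0),
            -c.rtp,
            c.transcript_id,
        )
    )
    return results


def count_consensus(transcripts: Sequence[Transcript], motif: str) -> int:
    """Number of transcripts whose SCC matches the motif exactly at the stop."""
    return sum(matches_consensus(t, motif) for t in transcripts)
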
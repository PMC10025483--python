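"""miRNA:target duplex alignment and compliance scoring.

A miRNA site on an mRNA is an ungapped window, of the miRNA's length,
whose sequence is (near-)reverse-complementary to the miRNA. Every window
of the transcript is scored with plant-style penalties: 0 for a
Watson-Crick pair, 0.5 for a G:U wobble, 1 for a mismatch, with weights
doubled across miRNA positions 2-13 (the region whose pairing AGO
requires for slicing). Windows at or below ``penalty_max`` (default 7.5)
are reported. AGO cleaves the target between the nucleotides opposite
miRNA positions 10 and 11; the predicted cleavage coordinate is the
transcript nucleotide paired to miRNA position 10.

The compliance score folds degradome evidence into the alignment quality:

    compliance = 2 * min(penalty, 7.5) + rank_penalty

where rank_penalty is 0 for a degradome cleavage site ranked 1 on its
transcript, 1 for ranks 2-3, 2 for ranks 4-10, and 3 for an unsupported
site (rank > 10 or no degradome signal). The score spans [0, 18]; lower
is better.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np

from .degradome import TranscriptProfile, site_rank_at

PENALTY_MAX_DEFAULT = 7.5
CORE_REGION = (2, 13)  # miRNA positions with doubled weights, inclusive
MISMATCH_WEIGHT = 1.0
WOBBLE_WEIGHT = 0.5
CLEAVAGE_MIRNA_POSITION = 10

_ENCODE = {"A": 0, "C": 1, "G": 2, "T": 3, "U": 3, "N": 4}
_COMPLEMENT = np.array([3, 2, 1, 0, 4], dtype=np.int8)  # A<->T, C<->G; N matches nothing


def _encode(seq: str) -> np.ndarray:
    try:
        return np.array([_ENCODE[b] for b in seq.upper()], dtype=np.int8)
    except KeyError as exc:
        raise ValueError(f"non-nucleotide character in sequence: {exc}") from exc


@dataclass(frozen=True)
class DuplexAlignment:
    """One candidate miRNA:mRNA duplex at one transcript window.

    ``per_position_state`` runs over miRNA positions 1..L (miRNA 5'->3');
    coordinates are 1-based inclusive on the transcript sense strand.
    """

    mirna_name: str
    transcript_id: str
    site_start: int
    site_end: int
    per_position_state: tuple[str, ...]
    penalty: float
    predicted_cleavage: int


@dataclass(frozen=True)
class TargetHit:
    alignment: DuplexAlignment
    site_rank: int | None
    raw_support: float
    normalized_support: float
    compliance: float


def _position_weights(length: int) -> np.ndarray:
    """Per-miRNA-position weight multipliers (1 or 2), 5'->3'."""
    pos = np.arange(1, length + 1)
    return np.where((pos >= CORE_REGION[0]) & (pos <= CORE_REGION[1]), 2.0, 1.0)


def align_duplex(
    mirna: str,
    transcript: str,
    mirna_name: str = "mirna",
    transcript_id: str = "transcript",
    penalty_max: float = PENALTY_MAX_DEFAULT,
) -> list[DuplexAlignment]:
    """Scan every ungapped transcript window against the miRNA.

    Returns alignments with penalty <= ``penalty_max``, sorted by
    (penalty, site_start). Transcripts shorter than the miRNA yield an
    empty list. U and T are interchangeable on both strands.
    """
    if not 18 <= len(mirna) <= 26:
        raise ValueError(f"miRNA length {len(mirna)} outside the 18-26 nt window")
    L = len(mirna)
    if len(transcript) < L:
        return []
    m = _encode(mirna)
    t = _encode(transcript)
    # Window index k pairs with miRNA position i = L - k (the miRNA lies
    # antiparallel to the mRNA), so the reversed miRNA aligns elementwise.
    mr = m[::-1]
    want = _COMPLEMENT[mr]  # transcript base that Watson-Crick pairs mr[k]
    windows = np.lib.stride_tricks.sliding_window_view(t, L)
    match = windows == want[None, :]
    # G:U wobble on the sense strand: mRNA G opposite miRNA U, or mRNA U
    # opposite miRNA G.
    wobble = ((windows == 2) & (mr[None, :] == 3)) | ((windows == 3) & (mr[None, :] == 2))
    weights = _position_weights(L)[::-1]  # into window coordinates
    cost = np.where(match, 0.0, np.where(wobble, WOBBLE_WEIGHT, MISMATCH_WEIGHT))
    penalties = cost @ weights
    keep = np.flatnonzero(penalties <= penalty_max + 1e-9)

    out = []
    for s0 in keep:
        states = []
        for i in range(1, L + 1):  # miRNA position, 5'->3'
            k = L - i
            if match[s0, k]:
                states.append("match")
            elif wobble[s0, k]:
                states.append("gu_wobble")
            else:
                states.append("mismatch")
        out.append(
            DuplexAlignment(
                mirna_name=mirna_name,
                transcript_id=transcript_id,
                site_start=int(s0) + 1,
                site_end=int(s0) + L,
                per_position_state=tuple(states),
                penalty=float(penalties[s0]),
                predicted_cleavage=int(s0) + 1 + (L - CLEAVAGE_MIRNA_POSITION),
            )
        )
    out.sort(key=lambda a: (a.penalty, a.site_start))
    return out


def rank_penalty(site_rank: int | None, has_support: bool) -> float:
    """Degradome-evidence component of the compliance score (0-3)."""
    if not has_support or site_rank is None:
        return 3.0
    if site_rank < 1:
        raise ValueError("site_rank must be >= 1")
    if site_rank == 1:
        return 0.0
    if site_rank <= 3:
        return 1.0
    if site_rank <= 10:
        return 2.0
    return 3.0


def compliance_score(penalty: float, site_rank: int | None = None, has_support: bool = True) -> float:
    """Composite target-quality score in [0, 18]; lower is better.

    2 * min(penalty, 7.5) + rank_penalty. The maximum 18 is attained at
    the penalty cap with no degradome support.
    """
    if penalty < 0:
        raise ValueError("penalty must be non-negative")
    return 2.0 * min(penalty, PENALTY_MAX_DEFAULT) + rank_penalty(site_rank, has_support)


def score_hit(
    alignment: DuplexAlignment,
    profile: TranscriptProfile | None,
    library_total: int | None = None,
) -> TargetHit:
    """Attach degradome evidence at the predicted cleavage site to an
    alignment and compute its compliance score.

    ``profile`` may be None (no degradome coverage of the transcript), in
    which case the site is unsupported and takes the full rank penalty.
    """
    if profile is None:
        return TargetHit(alignment, None, 0.0, 0.0, compliance_score(alignment.penalty, None, False))
    raw = float(profile.count_at(alignment.predicted_cleavage))
    rank = site_rank_at(profile, alignment.predicted_cleavage)
    normalized = raw * 1e6 / library_total if library_total else 0.0
    return TargetHit(
        alignment,
        rank,
        raw,
        normalized,
        compliance_score(alignment.penalty, rank, has_support=rank is not None),
    )


def select_best_targets(hits: Sequence[TargetHit], delta: float = 1.0) -> list[TargetHit]:
    """Best-first hit report: all hits within ``delta`` of the lowest
    compliance score (co-best ties always included). Empty input yields
    an empty report."""
    if not hits:
        return []
    ranked = sorted(hits, key=lambda h: h.compliance)
    best = ranked[0].compliance
    return [h for h in ranked if h.compliance <= best + delta]


def validate_cleavage(
    alignment: DuplexAlignment,
    profile: TranscriptProfile,
    window: int = 1,
) -> tuple[bool, int | None]:
    """Check the dominant degradome peak inside the site against the
    predicted cleavage position.

    Returns (validated, offset): validated iff a maximal-count position
    within [site_start, site_end] lies within +/- ``window`` nt of the
    predicted cleavage coordinate; offset is the signed distance of the
    nearest such peak (None when the site carries no signal).
    """
    lo, hi = alignment.site_start - 1, alignment.site_end  # 0-based half-open
    segment = profile.raw[lo:hi]
    if segment.sum() == 0:
        return False, None
    peak_positions = np.flatnonzero(segment == segment.max()) + alignment.site_start
    offsets = peak_positions - alignment.predicted_cleavage
    nearest = int(offsets[np.argmin(np.abs(offsets))])
    return bool(abs(nearest) <= window), nearest


def render_alignment(alignment: DuplexAlignment, mirna: str, transcript: str) -> str:
    """Three-line text duplex: mRNA 5'->3', pairing line ('|' match,
    'o' wobble, space mismatch), miRNA 3'->5'."""
    site = transcript[alignment.site_start - 1 : alignment.site_end]
    pairing_by_window = []
    L = len(mirna)
    for k in range(L):
        state = alignment.per_position_state[L - k - 1]
        pairing_by_window.append({"match": "|", "gu_wobble": "o"}.get(state, " "))
    return (
        f"5' {site} 3'  {alignment.transcript_id}:{alignment.site_start}-{alignment.site_end}\n"
        f"   {''.join(pairing_by_window)}\n"
        f"3' {mirna[::-1]} 5'  {alignment.mirna_name}"
    )


def scan_targets(
    mirnas: Mapping[str, str],
    transcripts: Mapping[str, str],
    profiles: Mapping[str, TranscriptProfile] | None = None,
    library_total: int | None = None,
    penalty_max: float = PENALTY_MAX_DEFAULT,
) -> dict[str, list[TargetHit]]:
    """Score every miRNA against every transcript; returns hits per miRNA.

    ``profiles`` maps transcript_id -> degradome profile of one library;
    transcripts without a profile count as unsupported.
    """
    out: dict[str, list[TargetHit]] = {}
    for name, mseq in mirnas.items():
        hits = []
        for tid, tseq in transcripts.items():
            for aln in align_duplex(mseq, tseq, name, tid, penalty_max):
                prof = profiles.get(tid) if profiles else None
                hits.append(score_hit(aln, prof, library_total))
        out[name] = sorted(hits, key=lambda h: (h.compliance, h.alignment.penalty))
    return out
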
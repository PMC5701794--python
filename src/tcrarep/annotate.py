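"""Read annotation: V/J assignment, germline error correction, CDR3 and N-region inference.

The model of a read is amplicon-like: it begins at the 5' end of a TRAV
segment, runs through the somatically generated V-J junction, and ends at the
3' end of a TRAJ segment.  Assignment is therefore ungapped and end-anchored
(V at the read's 5' end, J at its 3' end); indels are not modelled.

Sequencing errors in germline-templated positions are corrected back to the
germline base.  Because bases at the junction may be untemplated (N-region),
corrections are only applied more than three nucleotides before the predicted
end of the V match and more than three nucleotides after the predicted start
of the J match; the three junction-proximal positions on either side are never
touched.  Boundary prediction treats a mismatch as a correctable candidate
only when the next three aligned bases match germline again (an evidence run);
otherwise the junction is considered reached.  This makes correction
conservative: it can only restore germline-templated bases, never overwrite
plausible junction sequence.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, replace
from typing import Iterable

import numpy as np
from Bio.Seq import Seq

from .germline import AmbiguityGroup
from .keys import KeyScheme, clonotype_key

__all__ = [
    "RawRead",
    "AnnotatedSequence",
    "AssignmentResult",
    "CorrectionResult",
    "Cdr3Result",
    "AnnotationStats",
    "assign_segment",
    "correct_errors",
    "extract_cdr3",
    "estimate_n_bases",
    "annotate_read",
    "annotate_sample",
    "filter_singletons",
]

MATCH_SCORE = 1
MISMATCH_SCORE = -3
EVIDENCE_RUN = 3  # germline matches required after a mismatch to call it an error
PROTECTED_NT = 3  # junction-proximal window never corrected ("more than three")
MIN_SPAN = 12
MAX_MISMATCH_RATE = 0.10

_J_ANCHOR_AA = ("F", "W", "L")


@dataclass(frozen=True)
class RawRead:
    read_id: str
    nt_sequence: str
    sample_id: str = ""

    def __post_init__(self) -> None:
        if not self.nt_sequence or set(self.nt_sequence) - set("ACGT"):
            raise ValueError(f"{self.read_id}: read must be non-empty A/C/G/T")


@dataclass(frozen=True)
class AnnotatedSequence:
    """One read after V/J assignment, correction and CDR3/N-region inference."""

    read_id: str
    sample_id: str
    v_group: str
    j_group: str
    corrected_nt: str
    cdr3_nt: str
    cdr3_aa: str
    n_bases: int
    productive: bool
    corrections_applied: int


@dataclass(frozen=True)
class AssignmentResult:
    group_id: str
    span: tuple[int, int]  # 0-based half-open interval on the read
    mismatch_count: int
    assignable: bool


@dataclass(frozen=True)
class CorrectionResult:
    corrected_nt: str
    corrections_applied: int
    v_end: int  # predicted read position one past the last V-templated base
    j_start: int  # predicted read position of the first J-templated base
    overlap: bool  # predicted spans overlapped (junction-free read)


@dataclass(frozen=True)
class Cdr3Result:
    cdr3_nt: str
    cdr3_aa: str
    productive: bool
    ok: bool
    reason: str | None = None


@dataclass
class AnnotationStats:
    reads_in: int = 0
    unassignable: int = 0
    extraction_failed: int = 0
    non_productive: int = 0
    annotated: int = 0
    corrections_applied: int = 0


def _to_arr(seq: str) -> np.ndarray:
    return np.frombuffer(seq.encode("ascii"), dtype=np.uint8)


def _best_anchored(read: np.ndarray, ref: np.ndarray, end: str) -> tuple[int, int, int]:
    """Best ungapped alignment anchored at one end.

    Returns ``(span, mismatches, score)`` for the span maximizing the running
    +1/-3 match/mismatch score; ties resolved toward the shorter span.
    """
    limit = min(len(read), len(ref))
    if limit == 0:
        return 0, 0, 0
    if end == "prefix":
        eq = read[:limit] == ref[:limit]
    else:
        eq = read[-limit:][::-1] == ref[-limit:][::-1]
    scores = np.cumsum(np.where(eq, MATCH_SCORE, MISMATCH_SCORE))
    best = int(np.argmax(scores))  # first occurrence -> shortest span on ties
    span = best + 1
    mismatches = int(np.count_nonzero(~eq[:span]))
    return span, mismatches, int(scores[best])


def assign_segment(
    read: RawRead | str, groups: Iterable[AmbiguityGroup], kind: str
) -> AssignmentResult:
    """Assign the read to the V (5'-anchored) or J (3'-anchored) ambiguity group
    whose representative aligns with the best score; ties go to the longer
    span, then fewer mismatches, then the lexicographically first group id.

    The read is flagged unassignable when the best span is shorter than
    ``MIN_SPAN`` or its mismatch rate exceeds ``MAX_MISMATCH_RATE``.
    """
    seq = read.nt_sequence if isinstance(read, RawRead) else read
    arr = _to_arr(seq)
    candidates = [g for g in groups if g.kind == kind]
    if not candidates:
        raise ValueError(f"no ambiguity groups of kind {kind!r}")
    end = "prefix" if kind == "V" else "suffix"
    best = None
    for g in candidates:
        span, mism, score = _best_anchored(arr, _to_arr(g.nt_sequence), end)
        key = (-score, -span, mism, g.group_id)
        if best is None or key < best[0]:
            best = (key, g, span, mism, score)
    _, g, span, mism, score = best
    assignable = span >= MIN_SPAN and score > 0 and mism / span <= MAX_MISMATCH_RATE
    interval = (0, span) if kind == "V" else (len(seq) - span, len(seq))
    return AssignmentResult(g.group_id, interval, mism, assignable)


def _walk_v(read: str, v_seq: str) -> tuple[int, list[int]]:
    """5'-anchored walk: predicted V end and correctable-candidate positions."""
    limit = min(len(read), len(v_seq))
    candidates: list[int] = []
    i = 0
    while i < limit:
        if read[i] == v_seq[i]:
            i += 1
            continue
        if i + 1 + EVIDENCE_RUN <= limit and read[i + 1 : i + 1 + EVIDENCE_RUN] == v_seq[
            i + 1 : i + 1 + EVIDENCE_RUN
        ]:
            candidates.append(i)
            i += 1
        else:
            break
    return i, candidates


def _walk_j(read: str, j_seq: str) -> tuple[int, list[int]]:
    """3'-anchored walk: predicted J start and correctable-candidate positions."""
    n = len(read)
    off = n - len(j_seq)  # read position of the first germline J base
    lo = max(off, 0)
    candidates: list[int] = []
    i = n - 1
    while i >= lo:
        c = i - off
        if read[i] == j_seq[c]:
            i -= 1
            continue
        if i - EVIDENCE_RUN >= lo and read[i - EVIDENCE_RUN : i] == j_seq[c - EVIDENCE_RUN : c]:
            candidates.append(i)
            i -= 1
        else:
            break
    return i + 1, candidates


def correct_errors(read_nt: str, v_seq: str, j_seq: str) -> CorrectionResult:
    """Replace sequencing errors with germline bases outside the protected window.

    Within the V match, mismatches are replaced only at positions more than
    ``PROTECTED_NT`` nucleotides before the predicted V end; within the J
    match, only more than ``PROTECTED_NT`` nucleotides after the predicted J
    start.  If the predicted spans overlap (a junction-free read), nothing in
    the overlap is corrected and the result is flagged.
    """
    v_end, v_candidates = _walk_v(read_nt, v_seq)
    j_start, j_candidates = _walk_j(read_nt, j_seq)
    overlap = v_end > j_start
    off = len(read_nt) - len(j_seq)
    out = list(read_nt)
    applied = 0
    for p in v_candidates:
        if p <= v_end - (PROTECTED_NT + 1) and p < j_start:
            out[p] = v_seq[p]
            applied += 1
    for p in j_candidates:
        if p >= j_start + PROTECTED_NT and p >= v_end:
            out[p] = j_seq[p - off]
            applied += 1
    return CorrectionResult("".join(out), applied, v_end, j_start, overlap)


def _translate_frame(nt: str) -> str:
    usable = len(nt) - len(nt) % 3
    if usable == 0:
        return ""
    return str(Seq(nt[:usable]).translate())


def extract_cdr3(
    corrected_nt: str,
    v: AmbiguityGroup,
    j: AmbiguityGroup,
    v_span: tuple[int, int],
    j_span: tuple[int, int],
) -> Cdr3Result:
    """CDR3 from the first base of the V anchor Cys codon through the last base
    of the J anchor F/W/L codon, inclusive.

    Productive requires an in-frame junction (length divisible by 3), a
    translation starting with C and ending with F, W or L, and no stop codon.
    """
    n = len(corrected_nt)
    av = v.anchor_offset
    jpos = n - (len(j.nt_sequence) - j.anchor_offset)
    if av + 3 > v_span[1]:
        return Cdr3Result("", "", False, False, "v_anchor_outside_span")
    if jpos < j_span[0] or jpos + 3 > n:
        return Cdr3Result("", "", False, False, "j_anchor_outside_span")
    if av >= jpos + 3:
        return Cdr3Result("", "", False, False, "anchors_out_of_order")
    cdr3_nt = corrected_nt[av : jpos + 3]
    cdr3_aa = _translate_frame(cdr3_nt)
    productive = (
        len(cdr3_nt) % 3 == 0
        and len(cdr3_aa) >= 2
        and cdr3_aa[0] == "C"
        and cdr3_aa[-1] in _J_ANCHOR_AA
        and "*" not in cdr3_aa
    )
    return Cdr3Result(cdr3_nt, cdr3_aa, productive, True)


def estimate_n_bases(
    corrected_nt: str, v_seq: str, j_seq: str, cdr3_len: int | None = None
) -> int:
    """Untemplated junction bases under the maximal-extension convention.

    The maximal contiguous 5' stretch explained by germline V is attributed
    first; the maximal contiguous 3' stretch explained by germline J is then
    attributed on the remainder.  What is left is the N-region estimate.  Bases
    that happen to match a germline flank are attributed to the germline, so
    this is a parsimony estimate, not the generative insertion count.
    """
    n = len(corrected_nt)
    mv = min(n, len(v_seq))
    v_ext = 0
    while v_ext < mv and corrected_nt[v_ext] == v_seq[v_ext]:
        v_ext += 1
    lj = len(j_seq)
    mj = min(lj, n - v_ext)
    j_ext = 0
    while j_ext < mj and corrected_nt[n - 1 - j_ext] == j_seq[lj - 1 - j_ext]:
        j_ext += 1
    est = max(n - v_ext - j_ext, 0)
    if cdr3_len is not None:
        est = min(est, cdr3_len)
    return est


def annotate_read(
    read: RawRead,
    groups: list[AmbiguityGroup],
    correct: bool = True,
) -> tuple[AnnotatedSequence | None, str | None]:
    """Full per-read annotation; returns ``(annotated, None)`` or ``(None, reason)``."""
    v_res = assign_segment(read, groups, "V")
    if not v_res.assignable:
        return None, "unassignable_v"
    j_res = assign_segment(read, groups, "J")
    if not j_res.assignable:
        return None, "unassignable_j"
    by_id = {g.group_id: g for g in groups}
    v, j = by_id[v_res.group_id], by_id[j_res.group_id]
    if correct:
        corr = correct_errors(read.nt_sequence, v.nt_sequence, j.nt_sequence)
        corrected, n_corr = corr.corrected_nt, corr.corrections_applied
    else:
        corrected, n_corr = read.nt_sequence, 0
    cdr3 = extract_cdr3(corrected, v, j, v_res.span, j_res.span)
    if not cdr3.ok:
        return None, cdr3.reason
    n_est = estimate_n_bases(
        corrected, v.nt_sequence, j.nt_sequence, cdr3_len=len(cdr3.cdr3_nt)
    )
    return (
        AnnotatedSequence(
            read_id=read.read_id,
            sample_id=read.sample_id,
            v_group=v.group_id,
            j_group=j.group_id,
            corrected_nt=corrected,
            cdr3_nt=cdr3.cdr3_nt,
            cdr3_aa=cdr3.cdr3_aa,
            n_bases=n_est,
            productive=cdr3.productive,
            corrections_applied=n_corr,
        ),
        None,
    )


def annotate_sample(
    reads: Iterable[RawRead],
    groups: list[AmbiguityGroup],
    correct: bool = True,
) -> tuple[list[AnnotatedSequence], AnnotationStats]:
    """Annotate all reads of one sample.

    Identical read sequences are annotated once and the result reused, which
    makes deep amplicon samples (many duplicate reads per clonotype) cheap.
    """
    stats = AnnotationStats()
    cache: dict[str, tuple[AnnotatedSequence | None, str | None]] = {}
    out: list[AnnotatedSequence] = []
    for read in reads:
        stats.reads_in += 1
        hit = cache.get(read.nt_sequence)
        if hit is None:
            hit = annotate_read(read, groups, correct=correct)
            cache[read.nt_sequence] = hit
        ann, reason = hit
        if ann is None:
            if reason in ("unassignable_v", "unassignable_j"):
                stats.unassignable += 1
            else:
                stats.extraction_failed += 1
            continue
        ann = replace(ann, read_id=read.read_id, sample_id=read.sample_id)
        stats.corrections_applied += ann.corrections_applied
        if not ann.productive:
            stats.non_productive += 1
        stats.annotated += 1
        out.append(ann)
    return out, stats


def filter_singletons(
    annotated: list[AnnotatedSequence],
    key_scheme: KeyScheme = KeyScheme.FULL_TCRA,
) -> list[AnnotatedSequence]:
    """Keep only sequences whose clonotype key occurs at least twice in the sample.

    Mirrors the misread filter: sequences occurring once in a sequencing run
    are eliminated because a junction-window error cannot be corrected and
    would otherwise masquerade as a rare clonotype.
    """
    if not annotated:
        return []
    sample_ids = {a.sample_id for a in annotated}
    if len(sample_ids) > 1:
        raise ValueError(f"singleton filter expects one sample, got {sorted(sample_ids)}")
    counts = Counter(clonotype_key(a, key_scheme) for a in annotated)
    return [a for a in annotated if counts[clonotype_key(a, key_scheme)] >= 2]
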
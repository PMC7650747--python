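"""Genome termini and packaging-mechanism calls from read coverage.

Maps reads onto a genome with an exact k-mer seeded, ungapped mapper (the
genome is treated as circular, so headful-permuted reads map across the
origin), builds per-base depth and strand-specific read-start profiles, and
classifies the genome's ends from the two coverage signatures:

* a direct terminal repeat (DTR) shows as a contiguous interval of roughly
  doubled depth, delimited by single-base step changes, because the repeat
  is present twice per virion but once in the assembled genome;
* headful (*pac*) packaging shows as a read-start pileup at a single
  position -- the fixed first end of the packaging series -- while depth
  stays flat.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from .genome_io import reverse_complement
from .synthetic import ReadSet, seq_to_codes

DTR_LONG = "DTR_LONG"
DTR_SHORT = "DTR_SHORT"
HEADFUL_PAC = "HEADFUL_PAC"
UNDETERMINED = "UNDETERMINED"


@dataclass
class ReadAlignments:
    """Mapped-read locations on a (circularised) genome."""

    read_ids: list[str]
    starts: np.ndarray  # leftmost genome coordinate of the aligned interval
    strands: np.ndarray  # '+' / '-'
    identities: np.ndarray
    read_length: int
    genome_length: int
    n_reads_total: int

    @property
    def n_mapped(self) -> int:
        return len(self.read_ids)

    @property
    def mapped_fraction(self) -> float:
        return self.n_mapped / self.n_reads_total if self.n_reads_total else 0.0


@dataclass
class CoverageProfile:
    """Per-base depth and 5' read-start counts over a genome."""

    depth: np.ndarray
    starts_fwd: np.ndarray
    starts_rev: np.ndarray
    n_reads_total: int
    n_reads_mapped: int

    def __post_init__(self) -> None:
        if (self.depth < 0).any() or (self.starts_fwd < 0).any() or (self.starts_rev < 0).any():
            raise ValueError("negative counts in coverage profile")
        if int(self.starts_fwd.sum() + self.starts_rev.sum()) != self.n_reads_mapped:
            raise ValueError("start counts do not sum to n_reads_mapped")

    @property
    def genome_length(self) -> int:
        return self.depth.size


@dataclass
class TerminiCall:
    """Classification of a genome's ends / packaging mechanism."""

    klass: str
    dtr_interval: tuple[int, int] | None = None
    pac_position: int | None = None
    coverage_ratio: float | None = None
    start_peak_score: float | None = None

    def __post_init__(self) -> None:
        if self.dtr_interval is not None and self.pac_position is not None:
            raise ValueError("DTR interval and pac position are mutually exclusive")


def map_reads(
    reads: ReadSet | Sequence[tuple[str, str]],
    genome: str,
    seed_kmer: int = 15,
    min_identity: float = 0.90,
) -> ReadAlignments:
    """Assign each read its best location by exact k-mer seeding plus
    ungapped extension, on both strands of the circularised genome.

    Seeds are probed at non-overlapping offsets along the read, so a read
    with scattered errors still finds its locus as long as one seed k-mer is
    error-free.  Reads below ``min_identity`` over their full length stay
    unmapped; ties are broken towards the leftmost position (forward strand
    first).
    """
    if seed_kmer < 11:
        raise ValueError("seed_kmer must be >= 11")
    if isinstance(reads, ReadSet):
        items = list(zip(reads.ids, reads.sequences))
        n_total = len(reads)
    else:
        items = [(rid, seq) for rid, seq in reads]
        n_total = len(items)
    L = len(genome)
    if items:
        rl = len(items[0][1])
        if any(len(seq) != rl for _, seq in items):
            raise ValueError("all reads must have equal length")
        if L < rl:
            raise ValueError("genome shorter than read length")
    else:
        rl = 0

    ext = genome + genome[: max(rl, seed_kmer) - 1]
    ext_codes = seq_to_codes(ext)
    k = seed_kmer
    index: dict[str, list[int]] = {}
    for i in range(L):
        index.setdefault(ext[i : i + k], []).append(i)

    offsets = list(range(0, rl - k + 1, k)) if rl >= k else []
    out_ids: list[str] = []
    out_starts: list[int] = []
    out_strands: list[str] = []
    out_ident: list[float] = []

    for rid, seq in items:
        best_mm = rl + 1
        best_pos = -1
        best_strand = "+"
        for strand in ("+", "-"):
            s = seq if strand == "+" else reverse_complement(seq)
            codes = seq_to_codes(s)
            seen: set[int] = set()
            for off in offsets:
                for pos in index.get(s[off : off + k], ()):
                    cand = (pos - off) % L
                    if cand in seen:
                        continue
                    seen.add(cand)
                    mm = int(np.count_nonzero(ext_codes[cand : cand + rl] != codes))
                    if mm < best_mm or (mm == best_mm and (strand == best_strand and cand < best_pos)):
                        best_mm, best_pos, best_strand = mm, cand, strand
                if best_mm == 0:
                    break
            if best_mm == 0:
                break
        if best_pos >= 0 and (rl - best_mm) / rl >= min_identity:
            out_ids.append(rid)
            out_starts.append(best_pos)
            out_strands.append(best_strand)
            out_ident.append((rl - best_mm) / rl)

    return ReadAlignments(
        read_ids=out_ids,
        starts=np.asarray(out_starts, dtype=np.int64),
        strands=np.asarray(out_strands, dtype="U1"),
        identities=np.asarray(out_ident, dtype=float),
        read_length=rl,
        genome_length=L,
        n_reads_total=n_total,
    )


def build_coverage(alignments: ReadAlignments, genome_length: int | None = None) -> CoverageProfile:
    """Accumulate depth and strand-specific 5' start counts from alignments.

    Aligned intervals may wrap around the origin (circular mapping); the 5'
    start of a reverse-strand read is the rightmost base of its interval.
    """
    L = genome_length if genome_length is not None else alignments.genome_length
    rl = alignments.read_length
    starts = alignments.starts
    if starts.size and (starts.min() < 0 or starts.max() >= L):
        raise ValueError("alignment coordinate out of range")
    depth_diff = np.zeros(L + 1, dtype=np.int64)
    ends = starts + rl
    nowrap = ends <= L
    np.add.at(depth_diff, starts[nowrap], 1)
    np.add.at(depth_diff, ends[nowrap], -1)
    wrapped = ~nowrap
    if wrapped.any():
        np.add.at(depth_diff, starts[wrapped], 1)
        depth_diff[L] -= int(wrapped.sum())
        depth_diff[0] += int(wrapped.sum())
        np.add.at(depth_diff, ends[wrapped] - L, -1)
    depth = np.cumsum(depth_diff[:L])
    starts_fwd = np.zeros(L, dtype=np.int64)
    starts_rev = np.zeros(L, dtype=np.int64)
    is_fwd = alignments.strands == "+"
    np.add.at(starts_fwd, starts[is_fwd], 1)
    np.add.at(starts_rev, (starts[~is_fwd] + rl - 1) % L, 1)
    return CoverageProfile(
        depth=depth,
        starts_fwd=starts_fwd,
        starts_rev=starts_rev,
        n_reads_total=alignments.n_reads_total,
        n_reads_mapped=len(alignments.read_ids),
    )


def _circular_interval_mask(L: int, start: int, end: int) -> np.ndarray:
    mask = np.zeros(L, dtype=bool)
    if end <= L:
        mask[start:end] = True
    else:
        mask[start:] = True
        mask[: end - L] = True
    return mask


def _longest_circular_run(mask: np.ndarray) -> tuple[int, int] | None:
    """Longest run of True in a circular boolean array, as (start, length)."""
    L = mask.size
    if mask.all():
        return (0, L)
    if not mask.any():
        return None
    # rotate so the array starts on a False, making runs non-wrapping
    first_false = int(np.argmin(mask))
    rolled = np.roll(mask, -first_false)
    padded = np.concatenate(([False], rolled, [False])).astype(np.int8)
    d = np.diff(padded)
    starts = np.flatnonzero(d == 1)
    ends = np.flatnonzero(d == -1)
    lengths = ends - starts
    k = int(np.argmax(lengths))
    return ((int(starts[k]) + first_false) % L, int(lengths[k]))


def detect_dtr(
    profile: CoverageProfile,
    ratio_threshold: float = 1.6,
    min_repeat_bp: int = 200,
    smooth_window: int = 51,
    boundary_sharpness: float = 0.5,
) -> tuple[int, int] | None:
    """Locate a direct terminal repeat as a contiguous elevated-depth interval.

    The elevated plateau is first found on a smoothed circular depth profile
    (elevated = above the midpoint between the background median and its
    ``ratio_threshold`` multiple); each boundary is then refined to the
    largest single-base step change near the plateau edge -- repeat edges are
    sharp at single-base resolution in termini data, whereas sampling noise
    steps are small.  The interval qualifies if its median depth is at least
    ``ratio_threshold`` times the median of the remainder, it spans at least
    ``min_repeat_bp``, and it covers less than half the genome.  Returns a
    0-based half-open interval whose end may exceed the genome length to
    denote wrap-around, or ``None``.
    """
    if ratio_threshold <= 1.0:
        raise ValueError("ratio_threshold must exceed 1")
    depth = profile.depth
    L = depth.size
    if L == 0:
        raise ValueError("empty profile")
    if not depth.any():
        warnings.warn("all-zero coverage profile; no DTR call possible")
        return None
    from scipy.ndimage import uniform_filter1d

    w = min(smooth_window, max(1, L // 20))
    smoothed = uniform_filter1d(depth.astype(float), size=w, mode="wrap")
    background = float(np.median(depth))
    if background <= 0:
        return None
    cutoff = background * (1.0 + ratio_threshold) / 2.0
    run = _longest_circular_run(smoothed >= cutoff)
    if run is None:
        return None
    run_start, run_len = run
    if run_len < min_repeat_bp or run_len >= L // 2:
        return None

    diff = depth - np.roll(depth, 1)
    slack = w + 25

    def refine(center: int, sign: int) -> int:
        window = (np.arange(center - slack, center + slack + 1)) % L
        vals = sign * diff[window]
        return int(window[int(np.argmax(vals))])

    i_start = refine(run_start, +1)
    i_end = refine((run_start + run_len) % L, -1)
    length = (i_end - i_start) % L
    if length < min_repeat_bp or length >= L // 2:
        return None
    inside = _circular_interval_mask(L, i_start, i_start + length)
    med_in = float(np.median(depth[inside]))
    med_out = float(np.median(depth[~inside]))
    if med_out <= 0:
        qualifies = med_in > 0
    else:
        qualifies = med_in >= ratio_threshold * med_out
    if not qualifies:
        return None
    # "clearly delimitated at single base positions": both edges must carry a
    # depth step commensurate with the elevation itself.  A repeat boundary
    # steps by the full extra coverage in one base; gradually decaying
    # elevations (e.g. terminally redundant headful ends) do not.
    gap = med_in - med_out
    if diff[i_start] < boundary_sharpness * gap or -diff[i_end] < boundary_sharpness * gap:
        return None
    return (i_start, i_start + length)


def detect_pac(
    profile: CoverageProfile,
    peak_factor: float = 2.0,
    dtr: tuple[int, int] | None = None,
) -> int | None:
    """Locate a *pac* site as an outlier strand-specific read-start pileup.

    A position qualifies if its start count exceeds ``peak_factor`` times
    the 99.9th percentile of all other start counts on the same strand.
    Suppressed entirely when a DTR was already detected.
    """
    if dtr is not None:
        return None
    best_pos: int | None = None
    best_score = 0.0
    for arr in (profile.starts_fwd, profile.starts_rev):
        if arr.size < 2 or not arr.any():
            continue
        i = int(np.argmax(arr))
        others = np.delete(arr, i)
        threshold = peak_factor * max(float(np.percentile(others, 99.9)), 1.0)
        if arr[i] > threshold:
            score = arr[i] / threshold
            if score > best_score:
                best_score = score
                best_pos = i
    return best_pos


def classify_termini(
    profile: CoverageProfile,
    long_dtr_threshold_bp: int = 2000,
    ratio_threshold: float = 1.6,
    min_repeat_bp: int = 200,
    peak_factor: float = 2.0,
    min_mapped_reads: int = 1000,
) -> TerminiCall:
    """Classify a genome's termini from its coverage profile.

    A detected repeat of at least ``long_dtr_threshold_bp`` is called
    DTR_LONG, a shorter one DTR_SHORT; otherwise a start-pileup yields
    HEADFUL_PAC; with neither signature, or with too few mapped reads for a
    reliable call, the genome stays UNDETERMINED.
    """
    if profile.n_reads_mapped < min_mapped_reads:
        return TerminiCall(klass=UNDETERMINED)
    dtr = detect_dtr(profile, ratio_threshold=ratio_threshold, min_repeat_bp=min_repeat_bp)
    if dtr is not None:
        L = profile.depth.size
        length = (dtr[1] - dtr[0]) if dtr[1] <= L else (dtr[1] - dtr[0])
        inside = _circular_interval_mask(L, dtr[0], dtr[1])
        ratio = float(np.median(profile.depth[inside])) / max(
            float(np.median(profile.depth[~inside])), 1e-9
        )
        klass = DTR_LONG if length >= long_dtr_threshold_bp else DTR_SHORT
        return TerminiCall(klass=klass, dtr_interval=dtr, coverage_ratio=ratio)
    pac = detect_pac(profile, peak_factor=peak_factor)
    if pac is not None:
        arr = profile.starts_fwd if profile.starts_fwd[pac] >= profile.starts_rev[pac] else profile.starts_rev
        others = np.delete(arr, pac)
        threshold = peak_factor * max(float(np.percentile(others, 99.9)), 1.0)
        return TerminiCall(
            klass=HEADFUL_PAC,
            pac_position=pac,
            start_peak_score=float(arr[pac]) / threshold,
        )
    return TerminiCall(klass=UNDETERMINED)


def write_bedgraph(profile: CoverageProfile, chrom: str, path: str | Path) -> None:
    """Write per-base depth as a run-length-compressed BedGraph track."""
    depth = profile.depth
    with open(path, "w") as fh:
        if depth.size == 0:
            return
        run_start = 0
        for i in range(1, depth.size + 1):
            if i == depth.size or depth[i] != depth[run_start]:
                fh.write(f"{chrom}\t{run_start}\t{i}\t{int(depth[run_start])}\n")
                run_start = i


def write_sam(
    alignments: ReadAlignments,
    reads: ReadSet,
    genome_id: str,
    path: str | Path,
) -> None:
    """Export mapped reads as SAM (via pysam) for external inspection.

    Wrap-around alignments are reported at their leftmost coordinate without
    split records; this export is for interoperability, not re-analysis.
    """
    import pysam

    header = {
        "HD": {"VN": "1.6", "SO": "unsorted"},
        "SQ": [{"SN": genome_id, "LN": alignments.genome_length}],
    }
    seq_by_id = dict(zip(reads.ids, reads.sequences))
    with pysam.AlignmentFile(str(path), "w", header=header) as out:
        for rid, start, strand in zip(alignments.read_ids, alignments.starts, alignments.strands):
            a = pysam.AlignedSegment()
            a.query_name = rid
            seq = seq_by_id[rid]
            a.query_sequence = seq if strand == "+" else reverse_complement(seq)
            a.flag = 0 if strand == "+" else 16
            a.reference_id = 0
            a.reference_start = int(start)
            a.mapping_quality = 60
            a.cigarstring = f"{alignments.read_length}M"
            out.write(a)
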
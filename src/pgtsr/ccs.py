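"""Comprehensive chromosomal screening (CCS) from SNP-array observations.

Per-SNP copy signals (log2 of copy number over 2) are median-smoothed in a
sliding window, classified as loss / neutral / gain by fixed thresholds,
merged into segments, and rendered as a molecular karyotype string, e.g.
``1q44*1; 2q32.1q37.3*3`` for a loss of distal 1q44 with a reciprocal gain
of 2q32.1->qter. A chromosomally balanced sample renders as
``(1–22)*1,(XN)*1`` (the sex chromosomes are reported jointly as XN; the
notation is reproduced verbatim, including its ``*1``-for-disomy quirk).
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genome import GenomeBuild
from .observe import NO_CALL, ArrayObservation

BALANCED_KARYOTYPE = "(1–22)*1,(XN)*1"  # en-dash, as conventionally printed

DEFAULT_WINDOW = 15  # SNPs
DEFAULT_GAIN = 0.25  # log2 threshold
DEFAULT_LOSS = -0.30

# log2(copy/2) anchors for integer-copy assignment; copy 0 uses a deep
# pseudo-anchor since log2(0) is undefined.
_COPY_ANCHORS = {0: -2.0, 1: -1.0, 2: 0.0, 3: np.log2(1.5), 4: 1.0}


@dataclass
class CNVSegment:
    """One called copy-number segment (1-based inclusive coordinates)."""

    chrom: str
    start: int
    end: int
    copy: int
    mean_signal: float
    band_span: str = ""
    n_snps: int = 0

    def __post_init__(self):
        if self.start >= self.end:
            raise ValueError("segment start must precede end")
        if self.copy not in range(5):
            raise ValueError("copy must be in 0..4")


@dataclass
class MolecularKaryotype:
    string: str
    abnormal: list[CNVSegment] = field(default_factory=list)

    @property
    def balanced(self) -> bool:
        return not self.abnormal


def copy_signals(
    obs: ArrayObservation, panel_positions: dict[str, np.ndarray], chrom: str
) -> pd.DataFrame:
    """Per-SNP (position, copy_signal, allele_fraction) series for one
    chromosome, no-call sites masked out, sorted by position."""
    pos = panel_positions[chrom]
    keep = (obs.calls[chrom] != NO_CALL) & ~np.isnan(obs.copy_signal[chrom])
    df = pd.DataFrame(
        {
            "position": pos[keep],
            "copy_signal": obs.copy_signal[chrom][keep],
            "allele_fraction": obs.allele_fraction[chrom][keep],
        }
    )
    return df.sort_values("position", ignore_index=True)


def segment_copy(
    positions: np.ndarray,
    signal: np.ndarray,
    chrom: str,
    genome: GenomeBuild,
    window_snps: int = DEFAULT_WINDOW,
    gain_thresh: float = DEFAULT_GAIN,
    loss_thresh: float = DEFAULT_LOSS,
) -> list[CNVSegment]:
    """Segment one chromosome's copy signal into abnormal CNV segments.

    The signal is median-smoothed over ``window_snps`` SNPs (centered),
    each SNP classified loss/neutral/gain, adjacent same-class SNPs merged,
    and each abnormal run assigned the integer copy whose log2 anchor is
    nearest its mean smoothed signal. Segment boundaries fall at midpoints
    between the last and first SNPs of discordant runs; terminal runs extend
    to the chromosome ends. Only abnormal (copy != 2) segments are returned.
    """
    if window_snps < 5:
        raise ValueError("window must be at least 5 SNPs")
    if len(positions) < window_snps:
        raise ValueError("series shorter than the smoothing window")
    smooth = (
        pd.Series(signal).rolling(window_snps, center=True, min_periods=1).median().to_numpy()
    )
    klass = np.zeros(len(smooth), dtype=np.int8)
    klass[smooth > gain_thresh] = 1
    klass[smooth < loss_thresh] = -1

    segments: list[CNVSegment] = []
    run_start = 0
    chrom_len = genome.length(chrom)
    boundaries = []  # (first_idx, last_idx, class)
    for i in range(1, len(klass) + 1):
        if i == len(klass) or klass[i] != klass[run_start]:
            boundaries.append((run_start, i - 1, int(klass[run_start])))
            run_start = i
    for bi, (i0, i1, kl) in enumerate(boundaries):
        if kl == 0:
            continue
        start = 1 if bi == 0 else (int(positions[boundaries[bi - 1][1]]) + int(positions[i0])) // 2
        end = (
            chrom_len
            if bi == len(boundaries) - 1
            else (int(positions[i1]) + int(positions[boundaries[bi + 1][0]])) // 2
        )
        mean_sig = float(np.mean(smooth[i0 : i1 + 1]))
        copy = min(_COPY_ANCHORS, key=lambda c: abs(_COPY_ANCHORS[c] - mean_sig))
        if copy == 2:
            continue
        try:
            span = genome.band_span(chrom, start, end)
        except KeyError:
            span = ""
        segments.append(CNVSegment(chrom, start, end, copy, mean_sig, span, i1 - i0 + 1))
    return segments


def karyotype_string(
    segments: list[CNVSegment], genome: GenomeBuild, sex: str = "N"
) -> MolecularKaryotype:
    """Render abnormal segments as a molecular karyotype string.

    Each abnormal segment renders ``<chrom><bandStart>[<bandEnd>]*<copy>``
    (the end band omitted when equal), joined by "; "; with no abnormal
    segment the balanced notation is rendered verbatim.
    """
    abnormal = [s for s in segments if s.copy != 2]
    if not abnormal:
        return MolecularKaryotype(BALANCED_KARYOTYPE, [])

    def chrom_key(chrom: str):
        n = chrom.removeprefix("chr")
        return (0, int(n)) if n.isdigit() else (1, n)

    parts = []
    for seg in sorted(abnormal, key=lambda s: (chrom_key(s.chrom), s.start)):
        span = seg.band_span or genome.band_span(seg.chrom, seg.start, seg.end)
        parts.append(f"{seg.chrom.removeprefix('chr')}{span}*{seg.copy}")
    return MolecularKaryotype("; ".join(parts), abnormal)


_SEGMENT_RE = re.compile(r"^(\d+|X|Y)((?:[pq][\d.]*)+)\*(\d)$")
_BAND_RE = re.compile(r"[pq][\d.]*")


def band_range(genome: GenomeBuild, chrom: str, band_name: str) -> tuple[int, int]:
    """Coordinates of a named band."""
    for b in genome.cytobands:
        if b.chrom == chrom and b.name == band_name:
            return b.start, b.end
    raise KeyError(f"band {band_name} not found on {chrom}")


def parse_karyotype(string: str, genome: GenomeBuild) -> list[CNVSegment]:
    """Parse a molecular karyotype string back to segments (band-resolution
    coordinates). The balanced notation parses to an empty list."""
    if string == BALANCED_KARYOTYPE:
        return []
    out = []
    for part in string.split("; "):
        m = _SEGMENT_RE.match(part.strip())
        if not m:
            raise ValueError(f"unparseable karyotype segment {part!r}")
        chrom = f"chr{m.group(1)}"
        bands = _BAND_RE.findall(m.group(2))
        start = band_range(genome, chrom, bands[0])[0]
        end = band_range(genome, chrom, bands[-1])[1]
        out.append(CNVSegment(chrom, start, end, int(m.group(3)), float("nan"), m.group(2)))
    return out


def screen_sample(
    obs: ArrayObservation,
    panel_positions: dict[str, np.ndarray],
    genome: GenomeBuild,
    window_snps: int = DEFAULT_WINDOW,
    gain_thresh: float = DEFAULT_GAIN,
    loss_thresh: float = DEFAULT_LOSS,
) -> MolecularKaryotype:
    """Full CCS of one sample: segment every chromosome and render the
    molecular karyotype."""
    segments: list[CNVSegment] = []
    for chrom in panel_positions:
        series = copy_signals(obs, panel_positions, chrom)
        if len(series) < window_snps:
            continue
        segments.extend(
            segment_copy(
                series["position"].to_numpy(),
                series["copy_signal"].to_numpy(),
                chrom, genome, window_snps, gain_thresh, loss_thresh,
            )
        )
    return karyotype_string(segments, genome)


def balanced_or_unbalanced(karyotype: MolecularKaryotype) -> str:
    """'unbalanced' iff any abnormal segment was called."""
    return "balanced" if karyotype.balanced else "unbalanced"
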
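"""Independent straight-line reference for the gene-score rules, plus a
deterministic generator of gene/segment layouts used to drive it.

The reference works on plain tuples (mean, clipped_len, z) in genomic order
and encodes the rule text directly, without sharing any code with the
package implementation.
"""
import itertools

import numpy as np

from locuscn import WindowGrid
from locuscn.intervals import GenomicInterval
from locuscn.segment import Segment, SegmentList

W = 500
GRID = WindowGrid("c", 0, 50_000, W)


def reference_gene_score(segments, tau, boundary_len):
    """segments: list of (mean, clipped_len_bp, z_of_segment), genomic order.

    Returns (score, rule_name).
    """
    if len(segments) == 1:
        return segments[0][0], "single_segment"

    means = [m for m, _, _ in segments]
    n_gain = sum(1 for m in means if m >= tau)
    n_loss = sum(1 for m in means if m <= -tau)

    if n_gain == 0 and n_loss == 0:
        nonzero_signs = {np.sign(m) for m in means if m != 0}
        if len(nonzero_signs) <= 1:
            num = sum(m * L for m, L, _ in segments)
            den = sum(L for _, L, _ in segments)
            return num / den, "same_sign_merge"
        return 0.0, "zero_default"

    if n_gain > n_loss:
        majority = 1.0
    elif n_loss > n_gain:
        majority = -1.0
    else:
        return 0.0, "zero_default"

    discordant = [k for k, m in enumerate(means) if np.sign(m) == -majority]
    if not discordant:
        num = sum(m * L for m, L, _ in segments)
        den = sum(L for _, L, _ in segments)
        return num / den, "same_sign_merge"

    if len(discordant) == 1:
        k = discordant[0]
        mean_k, len_k, z_k = segments[k]
        if (k == 0 or k == len(segments) - 1) and len_k < boundary_len:
            if np.sign(z_k) == majority:
                others = [s for i, s in enumerate(segments) if i != k]
                num = sum(m * L for m, L, _ in others)
                den = sum(L for _, L, _ in others)
                return num / den, "boundary_zscore_rescue"
        return 0.0, "zero_default"

    return 0.0, "zero_default"


def build_case(means, first_clip, last_clip, z_val):
    """Materialize a layout as (SegmentList, gene, x_row, expected tuples).

    Interior segments span 4 windows each; the two boundary segments extend
    beyond the gene so their clipped length is set by the gene's endpoints.
    The x row is constant within each segment; boundary-segment windows are
    set to z_val so the z-score is controlled independently of the mean.
    """
    k = len(means)
    seg_windows = 4
    # segment window boundaries: [0, b1, ..., 100]
    bounds = [0]
    for i in range(k - 1):
        bounds.append(10 + (i + 1) * seg_windows)
    bounds.append(GRID.n_windows)
    segs = [
        Segment(a, b, m) for (a, b), m in zip(zip(bounds[:-1], bounds[1:]), means)
    ]
    sl = SegmentList("case", segs, GRID.n_windows)

    first_end_bp = bounds[1] * W
    last_start_bp = bounds[-2] * W
    if k == 1:
        gene = GenomicInterval("c", 2000, 2000 + first_clip)
        expected = [(means[0], first_clip, z_val)]
    else:
        gene = GenomicInterval("c", first_end_bp - first_clip,
                               last_start_bp + last_clip)
        expected = [(means[0], first_clip, z_val)]
        for m in means[1:-1]:
            expected.append((m, seg_windows * W, z_val))
        expected.append((means[-1], last_clip, z_val))

    x = np.empty(GRID.n_windows)
    for seg in segs:
        x[seg.start_window:seg.end_window] = seg.mean
    # control the z-score of both boundary segments
    x[segs[0].start_window:segs[0].end_window] = z_val
    x[segs[-1].start_window:segs[-1].end_window] = z_val
    return sl, gene, x, expected


def generate_cases():
    """Deterministic suite of layouts covering every rule branch."""
    cases = []
    m1 = [0.9, -0.9, 0.1, -0.1]
    for m in m1:
        cases.append(((m,), 1500, 1500, 0.3))
    means2 = list(itertools.product([0.9, -0.9, 0.2, -0.2], repeat=2))
    for mm in means2:
        for first_clip, last_clip in [(150, 700), (700, 150), (150, 150)]:
            for z in (0.3, -0.3):
                cases.append((mm, first_clip, last_clip, z))
    means3 = list(itertools.product([0.9, -0.9, 0.1], repeat=3))
    for mm in means3:
        for clips in [(150, 700), (700, 150)]:
            cases.append((mm, clips[0], clips[1], 0.3))
            cases.append((mm, clips[0], clips[1], -0.3))
    means4 = [
        (0.9, 0.8, 0.7, -0.1),
        (-0.9, -0.8, -0.7, 0.1),
        (0.9, -0.9, 0.9, -0.9),
        (0.1, 0.2, 0.3, 0.05),
        (0.9, 0.9, -0.9, -0.9),
        (-0.1, 0.9, 0.9, 0.9),
    ]
    for mm in means4:
        for z in (0.4, -0.4):
            cases.append((mm, 150, 150, z))
    return cases
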
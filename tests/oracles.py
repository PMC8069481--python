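"""Independent brute-force re-implementations used to cross-check scorers.

These scan every contiguous segment range literally against the written
definitions, with their own merging loop, and share no code with the package
implementations.
"""

from __future__ import annotations


def _merge_fixpoint(segs, max_gap):
    """Repeatedly merge the first adjacent same-state pair until stable."""
    segs = [list(s) for s in segs]  # [start, end, major, minor]
    changed = True
    while changed:
        changed = False
        for i in range(len(segs) - 1):
            a, b = segs[i], segs[i + 1]
            gap = b[0] - a[1] - 1
            if a[2] == b[2] and a[3] == b[3] and gap < max_gap:
                segs[i] = [a[0], b[1], a[2], a[3]]
                del segs[i + 1]
                changed = True
                break
    return [tuple(s) for s in segs]


def _per_chrom(profile):
    out = {}
    for seg in profile.segments:
        out.setdefault(seg.chrom, []).append(
            (seg.start_bp, seg.end_bp, seg.major_cn, seg.minor_cn)
        )
    return {k: sorted(v) for k, v in out.items()}


def _maximal_ranges(segs, pred, max_gap):
    """All maximal contiguous index ranges of pred-true segments with small gaps."""
    n = len(segs)
    ranges = []
    for i in range(n):
        for j in range(i, n):
            window = segs[i : j + 1]
            if not all(pred(s) for s in window):
                continue
            if any(
                window[k + 1][0] - window[k][1] - 1 >= max_gap
                for k in range(len(window) - 1)
            ):
                continue
            left_ok = (
                i == 0
                or not pred(segs[i - 1])
                or segs[i][0] - segs[i - 1][1] - 1 >= max_gap
            )
            right_ok = (
                j == n - 1
                or not pred(segs[j + 1])
                or segs[j + 1][0] - segs[j][1] - 1 >= max_gap
            )
            if left_ok and right_ok:
                ranges.append((segs[i][0], segs[j][1]))
    return ranges


def _is_loh(seg):
    return seg[3] == 0 and seg[2] >= 1


def _is_imbalanced(seg):
    return seg[2] != seg[3]


def oracle_hrd_loh(profile, assembly, constants):
    count = 0
    for chrom, segs in _per_chrom(profile).items():
        spec = assembly[chrom]
        if not spec.is_autosome:
            continue
        segs = _merge_fixpoint(segs, constants.lst_max_gap_bp)
        for lo, hi in _maximal_ranges(segs, _is_loh, constants.lst_max_gap_bp):
            whole = lo <= 1 and hi >= spec.length_bp
            if hi - lo + 1 > constants.hrd_loh_min_bp and not whole:
                count += 1
    return count


def oracle_tai(profile, assembly, constants):
    count = 0
    for chrom, segs in _per_chrom(profile).items():
        spec = assembly[chrom]
        if not spec.is_autosome:
            continue
        segs = _merge_fixpoint(segs, constants.lst_max_gap_bp)
        first, last = segs[0][0], segs[-1][1]
        for lo, hi in _maximal_ranges(segs, _is_imbalanced, constants.lst_max_gap_bp):
            if lo <= spec.centromere_end_bp and hi >= spec.centromere_start_bp:
                continue
            if lo == first:
                count += 1
            if hi == last:
                count += 1
    return count


def oracle_lst(profile, assembly, constants):
    count = 0
    for chrom, segs in _per_chrom(profile).items():
        spec = assembly[chrom]
        if not spec.is_autosome:
            continue
        segs = _merge_fixpoint(segs, constants.lst_max_gap_bp)
        cs, ce = spec.centromere_start_bp, spec.centromere_end_bp
        arms = {"p": [], "q": []}
        for start, end, major, minor in segs:
            if start < cs:
                arms["p"].append((start, min(end, cs - 1), major, minor))
            if end > ce:
                arms["q"].append((max(start, ce + 1), end, major, minor))
        for arm_segs in arms.values():
            for a, b in zip(arm_segs, arm_segs[1:]):
                span_a = a[1] - a[0] + 1
                span_b = b[1] - b[0] + 1
                gap = b[0] - a[1] - 1
                if (
                    span_a >= constants.lst_min_segment_bp
                    and span_b >= constants.lst_min_segment_bp
                    and gap < constants.lst_max_gap_bp
                    and (a[2], a[3]) != (b[2], b[3])
                ):
                    count += 1
    return count


# ---------------------------------------------------------------------------
# HR-gene allelic-status oracle: literal transcription of the enumerated
# combinations, structured as flat condition tables.


def oracle_allelic_status(g_lof, g_vus, s_lof, s_vus, s_loh, deep_del):
    """Expected (status, mechanism) for one gene's event tallies."""
    lof_table = [
        ("lof_1", g_lof >= 1 and s_loh),
        ("lof_2", g_lof >= 1 and s_lof >= 1),
        ("lof_3", s_lof >= 1 and s_loh),
        ("lof_4", s_lof >= 2),
        ("lof_5", deep_del),
    ]
    vus_table = [
        ("vus_1", g_lof >= 1 and s_vus >= 1),
        ("vus_2", s_lof >= 1 and s_vus >= 1),
        ("vus_3", s_vus >= 1 and s_loh),
    ]
    for mech, hit in lof_table:
        if hit:
            return ("biallelic_lof", mech)
    for mech, hit in vus_table:
        if hit:
            return ("biallelic_vus", mech)
    if g_lof or s_lof or s_vus or s_loh:
        return ("monoallelic", None)
    return ("none", None)


# ---------------------------------------------------------------------------
# exact signed-rank null via dynamic programming over sign flips


def oracle_signed_rank_p(diffs, alternative="greater"):
    """One-sided exact p for the signed-rank statistic by full enumeration."""
    import itertools

    import numpy as np
    from scipy.stats import rankdata

    diffs = np.asarray(diffs, dtype=float)
    diffs = diffs[diffs != 0]
    if alternative == "less":
        diffs = -diffs
    ranks = rankdata(np.abs(diffs))
    w_obs = ranks[diffs > 0].sum()
    n = len(diffs)
    hits = sum(
        1
        for signs in itertools.product((0, 1), repeat=n)
        if sum(r for r, s in zip(ranks, signs) if s) >= w_obs - 1e-12
    )
    return hits / 2.0**n
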
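"""Independent brute-force reference for the three scar counters.

Deliberately naive: works on plain lists of (start, end, major, minor)
tuples, enumerates candidate segments/runs/breakpoints and applies each
stated rule literally, without sharing any code with the package.
"""

from __future__ import annotations


def _sorted_merged(segs):
    """Sort and merge equal-copy abutting tuples (naive loop)."""
    segs = sorted(segs)
    out = []
    for seg in segs:
        if out:
            ps, pe, pM, pm = out[-1]
            s, e, M, m = seg
            if ps is not None and pe == s and pM == M and pm == m:
                out[-1] = (ps, e, M, m)
                continue
        out.append(seg)
    return out


def loh_count(segs, chrom_len, min_len=15_000_000):
    n = 0
    for start, end, major, minor in _sorted_merged(segs):
        if minor == 0 and end - start >= min_len and not (start == 0 and end == chrom_len):
            n += 1
    return n


def lst_count(segs, cen_start, cen_end, smooth_len=3_000_000, min_flank=10_000_000):
    # smoothing step: drop short fragments, then absorb near-adjacent equals
    big = [s for s in _sorted_merged(segs) if s[1] - s[0] >= smooth_len]
    absorbed = []
    for seg in big:
        if absorbed:
            ps, pe, pM, pm = absorbed[-1]
            s, e, M, m = seg
            if pM == M and pm == m and s - pe < smooth_len:
                absorbed[-1] = (ps, e, M, m)
                continue
        absorbed.append(seg)
    n = 0
    for i in range(len(absorbed) - 1):
        ls, le, lM, lm = absorbed[i]
        rs, re, rM, rm = absorbed[i + 1]
        if le - ls < min_flank:
            continue
        if re - rs < min_flank:
            continue
        if rs - le >= smooth_len:
            continue
        if le <= cen_end and rs >= cen_start:  # breakpoint at the centromere
            continue
        n += 1
    return n


def ntai_count(segs, chrom_len, cen_start, cen_end, min_len=11_000_000):
    merged = _sorted_merged(segs)
    # enumerate maximal contiguous runs of imbalanced segments
    runs = []
    i = 0
    while i < len(merged):
        if merged[i][2] != merged[i][3]:
            j = i
            while (
                j + 1 < len(merged)
                and merged[j + 1][2] != merged[j + 1][3]
                and merged[j + 1][0] == merged[j][1]
            ):
                j += 1
            runs.append((merged[i][0], merged[j][1]))
            i = j + 1
        else:
            i += 1
    n = 0
    for start, end in runs:
        if not (start == 0 or end == chrom_len):
            continue
        if start == 0 and end == chrom_len:
            continue
        if start < cen_start and end > cen_end:
            continue
        if end - start < min_len:
            continue
        n += 1
    return n
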
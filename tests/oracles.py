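"""Independent brute-force oracles shared by unit and acceptance tests.

Deliberately written loop-by-loop, without reusing any package internals,
so they stay an independent check on the vectorised implementations.
"""


def brute_force_events(dff, baseline, threshold, frame_rate, min_area, merge_gap):
    """Frame-by-frame threshold-crossing event finder (inclusive bounds)."""
    above = [(d - b) > threshold for d, b in zip(dff, baseline)]
    runs = []
    i, n = 0, len(dff)
    while i < n:
        if above[i]:
            j = i
            while j + 1 < n and above[j + 1]:
                j += 1
            runs.append([i, j])
            i = j + 1
        else:
            i += 1
    merged = []
    for start, stop in runs:
        if merged and start - merged[-1][1] - 1 < merge_gap:
            merged[-1][1] = stop
        else:
            merged.append([start, stop])
    events = []
    dt = 1.0 / frame_rate
    for start, stop in merged:
        seg = [dff[k] - baseline[k] for k in range(start, stop + 1)]
        if len(seg) > 1:
            area = sum((seg[k] + seg[k + 1]) / 2.0 * dt for k in range(len(seg) - 1))
        else:
            area = seg[0] * dt
        if area > min_area:
            events.append((start, stop))
    return events


def size_exclusion_oracle(area_um2):
    """Arithmetic size filter: excluded iff area < 0.05 or area > 1.2 µm²."""
    return not (area_um2 < 0.05 or area_um2 > 1.2)
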
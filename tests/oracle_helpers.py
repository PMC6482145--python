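"""Brute-force budget recomputation, independent of the pipeline.

Walks every observation and belt record with plain Python arithmetic (no
pandas, no pipeline helpers) so the test suite can check the pipeline's
line-scope results against an implementation that shares no code with it.
"""

from __future__ import annotations

import math


def brute_line_budget(line, echinoid_rate, rates, parrotfish_uses_rugosity=False):
    """Recompute one line's budget by direct census walking.

    Returns a dict with live_cover_pct, rugosity, gross_G, borer_G,
    parrotfish_G, echinoid_G, total_erosion_G, net_G.
    """
    sections = line.rugosity_sections
    R = (sections[0] + sections[1] + sections[2]) / 3.0

    coral_counts = {}
    cca = 0
    avail = 0
    live = 0
    for o in line.observations:
        if o.category == "live_coral":
            live += 1
            key = (o.taxon, o.morphology)
            coral_counts[key] = coral_counts.get(key, 0) + 1
        elif o.category == "cca":
            cca += 1
        if o.category in ("live_coral", "dead_coral", "reef_framework", "rubble"):
            avail += 1

    gross = 0.0
    for (taxon, morph), n in sorted(
        coral_counts.items(), key=lambda kv: (kv[0][0] or "", kv[0][1])
    ):
        ci = rates.lookup_ci(taxon, morph)
        xi = 100.0 * n / 100.0
        gross += R * (xi / 100.0) * (ci * 10.0)
    if cca > 0 and rates.cca_ci > 0:
        gross += R * ((100.0 * cca / 100.0) / 100.0) * (rates.cca_ci * 10.0)

    f_avail = avail / 100.0
    borer = R * f_avail * (rates.macro_borer_rate + rates.micro_borer_rate)
    parrot = rates.parrotfish_rate * f_avail * (R if parrotfish_uses_rugosity else 1.0)
    total = borer + parrot + echinoid_rate
    return {
        "live_cover_pct": 100.0 * live / 100.0,
        "rugosity": R,
        "gross_G": gross,
        "borer_G": borer,
        "parrotfish_G": parrot,
        "echinoid_G": echinoid_rate,
        "total_erosion_G": total,
        "net_G": gross - total,
    }


def brute_belt_rate(belt, rates):
    """Recompute one belt's echinoid rate by direct record walking."""
    size_sum = {}
    counts = {}
    for genus, size, count in belt.records:
        size_sum[genus] = size_sum.get(genus, 0.0) + size * count
        counts[genus] = counts.get(genus, 0) + count
    rate = 0.0
    for genus, n in counts.items():
        if n == 0:
            continue
        a, b = rates.echinoid_coeffs[genus]
        X = size_sum[genus] / n
        e = n / belt.area_m2
        rate += (a * X**b) * e * (365.0 / 60.0) / 1000.0
    return rate


def brute_echinoid_by_transect(belts, rates, transects):
    """Per-transect echinoid rate with reef-wide mean fallback."""
    per_transect = {}
    all_rates = []
    for belt in belts:
        r = brute_belt_rate(belt, rates)
        per_transect.setdefault(belt.transect_id, []).append(r)
        all_rates.append(r)
    reef_mean = sum(all_rates) / len(all_rates) if all_rates else 0.0
    out = {}
    for t in transects:
        if t in per_transect:
            rs = per_transect[t]
            out[t] = sum(rs) / len(rs)
        else:
            out[t] = reef_mean
    return out


def mean_sd(values):
    n = len(values)
    m = sum(values) / n
    if n < 2:
        return m, float("nan")
    return m, math.sqrt(sum((v - m) ** 2 for v in values) / (n - 1))
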
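"""Independent brute-force evaluation of the six entropy/complexity measures.

Deliberately written with stdlib Counter/math only, with no reference to the
package's own code paths, so test comparisons against it are meaningful.
"""

import math
from collections import Counter


def oracle_metrics(values, nodata=None, hmax_mode="log2"):
    """All six measures of a DN multiset, computed the slow explicit way."""
    vals = [int(v) for v in values if nodata is None or v != nodata]
    if not vals:
        raise ValueError("no valid values")
    counts = Counter(vals)
    total = len(vals)
    n = len(counts)
    probs = [c / total for c in counts.values()]
    hmax = math.log2(n) if hmax_mode == "log2" else float(n)
    he = -sum(p * math.log2(p) for p in probs)
    v = he / hmax if hmax > 0 else 0.0
    v = min(v, 1.0)
    d = sum((p - 1.0 / n) ** 2 for p in probs)
    return {
        "N": n,
        "Hmax": hmax,
        "He": he,
        "He_Hmax": v,
        "D": d,
        "SDL": v * (1.0 - v),
        "LMC": v * d,
    }


def oracle_from_counts(counts, hmax_mode="log2"):
    """Same measures from a value -> count mapping (no multiset expansion)."""
    if not counts:
        raise ValueError("no values")
    total = sum(counts.values())
    n = len(counts)
    probs = [c / total for c in counts.values()]
    hmax = math.log2(n) if hmax_mode == "log2" else float(n)
    he = -sum(p * math.log2(p) for p in probs)
    v = min(he / hmax, 1.0) if hmax > 0 else 0.0
    d = sum((p - 1.0 / n) ** 2 for p in probs)
    return {
        "N": n,
        "Hmax": hmax,
        "He": he,
        "He_Hmax": v,
        "D": d,
        "SDL": v * (1.0 - v),
        "LMC": v * d,
    }
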
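"""Independent brute-force oracles for the 49 window features.

Naive pure-Python loop implementations, kept deliberately separate from the
package code paths so the two can be compared on random windows.
"""

from __future__ import annotations

import cmath
import math


def naive_vm(xyz) -> list[float]:
    return [math.sqrt(x * x + y * y + z * z) for x, y, z in xyz]


def naive_mean(v) -> float:
    return sum(v) / len(v)


def naive_sd(v) -> float:
    m = naive_mean(v)
    return math.sqrt(sum((x - m) ** 2 for x in v) / (len(v) - 1))


def naive_quantile(v, q) -> float:
    """Linear interpolation between order statistics (the 'type 7' rule)."""
    s = sorted(v)
    h = (len(s) - 1) * q
    lo = math.floor(h)
    hi = math.ceil(h)
    return s[lo] + (h - lo) * (s[hi] - s[lo])


def naive_signal_stats(v) -> dict[str, float]:
    n = len(v)
    mean = naive_mean(v)
    sd = naive_sd(v)
    cv = 0.0 if abs(mean) < 1e-6 else 100.0 * sd / abs(mean)
    m2 = sum((x - mean) ** 2 for x in v) / n
    m3 = sum((x - mean) ** 3 for x in v) / n
    m4 = sum((x - mean) ** 4 for x in v) / n
    if m2 < 1e-12:
        skew = kurt = 0.0
    else:
        skew = m3 / m2 ** 1.5
        kurt = m4 / m2 ** 2
    return {"mean": mean, "sd": sd, "cv": cv, "min": min(v), "max": max(v),
            "q25": naive_quantile(v, 0.25), "q75": naive_quantile(v, 0.75),
            "third": m3, "fourth": m4, "skewness": skew, "kurtosis": kurt}


def naive_angles(xyz) -> list[float]:
    out = []
    for (x, _, _), vm in zip(xyz, naive_vm(xyz)):
        r = 0.0 if vm == 0 else max(-1.0, min(1.0, x / vm))
        out.append(math.degrees(math.asin(r)))
    return out


def naive_dft_moduli(v) -> list[float]:
    """O(n²) DFT moduli at positive frequencies k = 1 .. floor(n/2)."""
    n = len(v)
    out = []
    for k in range(1, n // 2 + 1):
        acc = sum(x * cmath.exp(-2j * math.pi * k * i / n)
                  for i, x in enumerate(v))
        out.append(abs(acc))
    return out


def naive_freq_features(v, rate) -> tuple[float, float, float]:
    n = len(v)
    moduli = naive_dft_moduli(v)
    freqs = [k * rate / n for k in range(1, n // 2 + 1)]
    total = sum(moduli)
    if all(m < 1e-12 for m in moduli):
        return 0.0, 0.0, 0.0
    p625 = sum(m for m, f in zip(moduli, freqs) if 0.6 <= f <= 2.5) / total
    best = max(range(len(moduli)), key=lambda k: moduli[k])
    # explicit lowest-frequency tie-break
    for k in range(best):
        if moduli[k] == moduli[best]:
            best = k
            break
    return p625, freqs[best], moduli[best] / total


def naive_all_features(xyz, rate) -> dict[str, float]:
    """All 49 features, named exactly as the package names them."""
    vm = naive_vm(xyz)
    xs = [p[0] for p in xyz]
    ys = [p[1] for p in xyz]
    zs = [p[2] for p in xyz]
    names = {"vm": ("mvm", "sdvm", "cv_vm", "min_vm", "max_vm", "lower_vm_25",
                    "upper_vm_75", "third_vm", "fourth_vm", "skewness_vm",
                    "kurtosis_vm")}
    for ax in "xyz":
        names[ax] = (f"mean_{ax}", f"sd_{ax}", f"cv_{ax}", f"min_{ax}",
                     f"max_{ax}", f"lower_{ax}_25", f"upper_{ax}_75",
                     f"third_{ax}", f"fourth_{ax}", f"skewness_{ax}",
                     f"kurtosis_{ax}")
    order = ("mean", "sd", "cv", "min", "max", "q25", "q75", "third",
             "fourth", "skewness", "kurtosis")
    out = {}
    for sig, series in (("vm", vm), ("x", xs), ("y", ys), ("z", zs)):
        stats = naive_signal_stats(series)
        for key, name in zip(order, names[sig]):
            out[name] = stats[key]
    angles = naive_angles(xyz)
    out["mangle"] = naive_mean(angles)
    out["sdangle"] = naive_sd(angles)
    out["p625"], out["df"], out["fpdf"] = naive_freq_features(vm, rate)
    return out
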
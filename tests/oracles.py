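"""Independent brute-force oracles used by the test suite.

Deliberately naive implementations (nested loops, direct formula
transcription) kept separate from the package so they cannot share bugs
with the vectorized code they check.
"""

from __future__ import annotations

import math

import numpy as np
from scipy.stats import norm


def sampen_naive(x, m=2, r_frac=0.2):
    x = np.asarray(x, dtype=float)
    r = r_frac * x.std()
    n = len(x)
    nt = n - m  # same template basis for lengths m and m+1
    b = a = 0
    for i in range(nt):
        for j in range(i + 1, nt):
            if max(abs(x[i + k] - x[j + k]) for k in range(m)) <= r:
                b += 1
            if max(abs(x[i + k] - x[j + k]) for k in range(m + 1)) <= r:
                a += 1
    if b == 0 or a == 0:
        return float("nan")
    return -math.log(a / b)


def fuzzen_naive(x, m=2, r_frac=0.2, exponent=2.0):
    x = np.asarray(x, dtype=float)
    r = r_frac * x.std()

    def phi(mm):
        n = len(x) - mm + 1
        tpls = [x[i : i + mm] - np.mean(x[i : i + mm]) for i in range(n)]
        sims = []
        for i in range(n):
            for j in range(i + 1, n):
                d = max(abs(tpls[i][k] - tpls[j][k]) for k in range(mm))
                sims.append(math.exp(-((d / r) ** exponent)))
        return float(np.mean(sims))

    return math.log(phi(m)) - math.log(phi(m + 1))


def dispen_naive(x, m=2, c=6):
    x = np.asarray(x, dtype=float)
    y = norm.cdf(x, loc=x.mean(), scale=x.std())
    z = np.clip(np.round(c * y + 0.5).astype(int), 1, c)
    patterns = {}
    for i in range(len(z) - m + 1):
        key = tuple(z[i : i + m])
        patterns[key] = patterns.get(key, 0) + 1
    total = sum(patterns.values())
    h = -sum((v / total) * math.log(v / total) for v in patterns.values())
    return h / math.log(c**m)


def hrv_time_naive(nn):
    """Direct transcription of the 13 PPI time-domain definitions."""
    nn = list(map(float, nn))
    n = len(nn)
    mean = sum(nn) / n
    diffs = [nn[i + 1] - nn[i] for i in range(n - 1)]
    mean_d = sum(diffs) / len(diffs)
    sdnn = math.sqrt(sum((v - mean) ** 2 for v in nn) / (n - 1))
    sdsd = (
        math.sqrt(sum((d - mean_d) ** 2 for d in diffs) / (len(diffs) - 1))
        if len(diffs) > 1
        else 0.0
    )
    rmssd = math.sqrt(sum(d * d for d in diffs) / len(diffs))
    nn50 = sum(1 for d in diffs if abs(d) > 0.050)
    nn20 = sum(1 for d in diffs if abs(d) > 0.020)
    return {
        "Mean_NN": mean,
        "Max_PR": 60.0 / min(nn),
        "Min_PR": 60.0 / max(nn),
        "SDNN": sdnn,
        "CVNNI": sdnn / mean,
        "SDSD": sdsd,
        "CVSD": rmssd / mean,
        "NN50": float(nn50),
        "pNN50": 100.0 * nn50 / len(diffs),
        "NN20": float(nn20),
        "pNN20": 100.0 * nn20 / len(diffs),
        "RMSSD": rmssd,
        "Range_NN": max(nn) - min(nn),
    }
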
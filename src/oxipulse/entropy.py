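"""Template-matching entropy measures for short physiological series.

Sample entropy (Richman & Moorman), fuzzy entropy (exponential membership
on mean-removed templates) and normalized dispersion entropy (normal-CDF
class mapping). All three quantify pattern irregularity: low values for
regular waveforms, high for irregular ones. Implementations are vectorized
O(n^2); tests hold them against naive nested-loop oracles.

Conventions fixed here (the literature varies):

* tolerance ``r`` is specified as a fraction of the series SD
  (population SD); matches use Chebyshev distance with ``d <= r``;
* both template lengths m and m+1 are counted over the same index range
  ``0 .. n - m*delay - 2`` so the ratio compares like with like;
* a zero-variance series returns 0.0 for all three measures;
* sample entropy with zero m+1 matches returns ``nan`` (undefined) and the
  caller flags the segment.
"""

from __future__ import annotations

import numpy as np
from scipy.stats import norm

from .config import EntropyParams


def _embed(x: np.ndarray, m: int, delay: int) -> np.ndarray:
    n = x.size - (m - 1) * delay
    if n <= 0:
        raise ValueError(f"series too short for m={m}, delay={delay}")
    idx = np.arange(n)[:, None] + delay * np.arange(m)[None, :]
    return x[idx]


def _chebyshev_pairs(templates: np.ndarray) -> np.ndarray:
    """Condensed upper-triangle Chebyshev distances between template rows."""
    d = np.abs(templates[:, None, :] - templates[None, :, :]).max(axis=2)
    iu = np.triu_indices(templates.shape[0], k=1)
    return d[iu]


def sample_entropy(x: np.ndarray, params: EntropyParams | None = None) -> float:
    """SampEn = -ln(A/B): A, B = template match counts at lengths m+1, m."""
    p = params or EntropyParams()
    x = np.asarray(x, dtype=float)
    if x.size < 10 * p.m:
        raise ValueError(f"need at least {10 * p.m} samples for m={p.m}")
    sd = x.std()
    if sd == 0:
        return 0.0
    r = p.r * sd
    n_templates = x.size - p.m * p.delay  # common basis for both lengths
    xm = _embed(x, p.m, p.delay)[:n_templates]
    xm1 = _embed(x, p.m + 1, p.delay)[:n_templates]
    b = np.count_nonzero(_chebyshev_pairs(xm) <= r)
    a = np.count_nonzero(_chebyshev_pairs(xm1) <= r)
    if b == 0 or a == 0:
        return float("nan")
    return float(-np.log(a / b))


def fuzzy_entropy(x: np.ndarray, params: EntropyParams | None = None) -> float:
    """FuzzEn with membership exp(-(d/r)^n) on mean-removed templates."""
    p = params or EntropyParams()
    x = np.asarray(x, dtype=float)
    if x.size < 10 * p.m:
        raise ValueError(f"need at least {10 * p.m} samples for m={p.m}")
    sd = x.std()
    if sd == 0:
        return 0.0
    r = p.r * sd

    def phi(m: int) -> float:
        tpl = _embed(x, m, p.delay)
        tpl = tpl - tpl.mean(axis=1, keepdims=True)
        d = _chebyshev_pairs(tpl)
        return float(np.exp(-((d / r) ** p.fuzzy_exponent)).mean())

    return float(np.log(phi(p.m)) - np.log(phi(p.m + 1)))


def dispersion_entropy(x: np.ndarray, params: EntropyParams | None = None) -> float:
    """Normalized dispersion entropy: Shannon entropy of the frequencies of
    m-length dispersion patterns after normal-CDF mapping to c classes,
    divided by ln(c^m)."""
    p = params or EntropyParams()
    x = np.asarray(x, dtype=float)
    if x.size < 10 * p.m:
        raise ValueError(f"need at least {10 * p.m} samples for m={p.m}")
    sd = x.std()
    if sd == 0:
        return 0.0
    y = norm.cdf(x, loc=x.mean(), scale=sd)
    classes = np.clip(np.round(p.c * y + 0.5).astype(int), 1, p.c)
    patterns = _embed(classes, p.m, p.delay)
    # encode each pattern as an integer in base c
    codes = (patterns - 1) @ (p.c ** np.arange(p.m))
    counts = np.bincount(codes, minlength=p.c**p.m).astype(float)
    freqs = counts[counts > 0] / counts.sum()
    return float(-(freqs * np.log(freqs)).sum() / np.log(float(p.c**p.m)))
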
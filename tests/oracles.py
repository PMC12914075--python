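"""Independent brute-force oracles shared by the test suites."""

import numpy as np
from scipy import stats


def score_test_oracle(counts, scores):
    """Brute-force trend score test for a 2 x k binomial table.

    Numerically differentiates the binomial log-likelihood under the trend
    alternative p_j = expit(a + b * s_j) at the null MLE (b = 0) to obtain
    the efficient score statistic, referred to chi-square(1). This is an
    independent route to the same asymptotic reference the trend test in
    the package uses.
    """
    x = np.asarray(counts[0], float)
    nj = np.asarray(counts, float).sum(axis=0)
    s = np.asarray(scores, float)
    pbar = x.sum() / nj.sum()
    a0 = np.log(pbar / (1 - pbar))

    def loglik(a, b):
        eta = a + b * s
        p = 1 / (1 + np.exp(-eta))
        return float((x * np.log(p) + (nj - x) * np.log1p(-p)).sum())

    h = 1e-5
    u = (loglik(a0, h) - loglik(a0, -h)) / (2 * h)
    l00 = loglik(a0, 0)
    i_bb = -(loglik(a0, h) - 2 * l00 + loglik(a0, -h)) / h ** 2
    i_aa = -(loglik(a0 + h, 0) - 2 * l00 + loglik(a0 - h, 0)) / h ** 2
    i_ab = -(loglik(a0 + h, h) - loglik(a0 + h, -h)
             - loglik(a0 - h, h) + loglik(a0 - h, -h)) / (4 * h ** 2)
    stat = u ** 2 / (i_bb - i_ab ** 2 / i_aa)
    return float(stats.chi2.sf(stat, 1))


def per_subject_ols_slopes(long):
    """Unshrunk per-subject OLS slopes from long (subject, time, value)."""
    out = {}
    for sid, grp in long.groupby("subject"):
        t = grp["time"].to_numpy(float)
        v = grp["value"].to_numpy(float)
        tc = t - t.mean()
        out[sid] = float((tc * v).sum() / (tc ** 2).sum())
    import pandas as pd

    return pd.Series(out)
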
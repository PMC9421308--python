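"""Independent brute-force oracles used by the tests."""

import numpy as np


def grid_reml_tau2(y, se, hi=10.0, step=1e-4):
    """Maximise the restricted log-likelihood of y_i ~ N(mu, se_i^2 + tau2)
    by brute-force grid search over tau2 in [0, hi]."""
    y = np.asarray(y, dtype=float)
    v = np.asarray(se, dtype=float) ** 2
    tau2 = np.arange(0.0, hi + step, step)
    vt = v[None, :] + tau2[:, None]
    w = 1.0 / vt
    sw = w.sum(axis=1)
    mu = (w * y[None, :]).sum(axis=1) / sw
    ll = -0.5 * (np.log(vt).sum(axis=1) + np.log(sw)
                 + (w * (y[None, :] - mu[:, None]) ** 2).sum(axis=1))
    best = int(np.argmax(ll))
    tau2_hat = float(tau2[best])
    wb = 1.0 / (v + tau2_hat)
    pooled = float(np.sum(wb * y) / np.sum(wb))
    return tau2_hat, pooled


def exhaustive_signflip_maxt(deltas):
    """Exact max-T FWER p-values by enumerating all 2^n sign flips of the
    patients' delta vectors (standardised signed-rank statistic)."""
    from itertools import product

    from scipy.stats import rankdata

    deltas = np.asarray(deltas, dtype=float)
    n_pat, n_prot = deltas.shape
    signed = np.zeros_like(deltas)
    sd = np.empty(n_prot)
    for j in range(n_prot):
        d = deltas[:, j]
        ok = np.isfinite(d) & (d != 0)
        n = ok.sum()
        r = rankdata(np.abs(d[ok]))
        signed[ok, j] = r * np.sign(d[ok])
        sd[j] = np.sqrt(n * (n + 1) * (2 * n + 1) / 6.0) if n else np.inf
    obs = np.abs(signed.sum(axis=0) / sd)
    maxes = []
    for flips in product([-1.0, 1.0], repeat=n_pat):
        f = np.asarray(flips)
        maxes.append(np.abs((f @ signed) / sd).max())
    maxes = np.asarray(maxes)
    return np.array([(maxes >= o).mean() for o in obs])
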
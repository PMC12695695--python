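"""Independent brute-force reference implementations used to validate the
vectorized metrics.  Deliberately written as plain loops over voxels so they
share no code path with the package."""

import itertools

import numpy as np


def mae_loop(a, b, mask):
    total, n = 0.0, 0
    for idx in np.ndindex(a.shape):
        if mask[idx]:
            total += abs(float(a[idx]) - float(b[idx]))
            n += 1
    return total / n


def psnr_loop(a, b, mask, data_range):
    total, n = 0.0, 0
    for idx in np.ndindex(a.shape):
        if mask[idx]:
            total += (float(a[idx]) - float(b[idx])) ** 2
            n += 1
    mse = total / n
    if mse == 0:
        return float("inf")
    return 10.0 * np.log10(data_range ** 2 / mse)


def ssim_loop(a, b, mask, window, k1, k2, data_range):
    """Sliding-window SSIM averaged over in-mask interior window centres."""
    r = window // 2
    c1 = (k1 * data_range) ** 2
    c2 = (k2 * data_range) ** 2
    vals = []
    for i in range(r, a.shape[0] - r):
        for j in range(r, a.shape[1] - r):
            for k in range(r, a.shape[2] - r):
                if not mask[i, j, k]:
                    continue
                pa = a[i - r:i + r + 1, j - r:j + r + 1, k - r:k + r + 1].ravel()
                pb = b[i - r:i + r + 1, j - r:j + r + 1, k - r:k + r + 1].ravel()
                mu_a, mu_b = pa.mean(), pb.mean()
                var_a = pa.var()
                var_b = pb.var()
                cov = ((pa - mu_a) * (pb - mu_b)).mean()
                vals.append(((2 * mu_a * mu_b + c1) * (2 * cov + c2))
                            / ((mu_a ** 2 + mu_b ** 2 + c1) * (var_a + var_b + c2)))
    return float(np.mean(vals))


def dice_loop(a, b):
    inter = na = nb = 0
    for idx in np.ndindex(a.shape):
        if a[idx]:
            na += 1
        if b[idx]:
            nb += 1
        if a[idx] and b[idx]:
            inter += 1
    if na + nb == 0:
        return 1.0
    return 2.0 * inter / (na + nb)


def hausdorff_loop(a, b, spacing, percentile=100.0):
    """All-pairs directed distances, symmetrized by the max."""
    pa = np.argwhere(a) * np.asarray(spacing)
    pb = np.argwhere(b) * np.asarray(spacing)

    def directed(src, dst):
        return np.array([np.min(np.linalg.norm(dst - p, axis=1)) for p in src])

    d_ab = directed(pa, pb)
    d_ba = directed(pb, pa)
    if percentile == 100.0:
        return max(d_ab.max(), d_ba.max())
    return max(np.percentile(d_ab, percentile), np.percentile(d_ba, percentile))


def wilcoxon_exact_two_sided(diff):
    """Exact two-sided signed-rank p-value by enumerating all sign patterns
    (no ties / zeros assumed)."""
    diff = np.asarray(diff, dtype=float)
    n = diff.size
    ranks = np.argsort(np.argsort(np.abs(diff))) + 1.0
    w_plus = float(ranks[diff > 0].sum())
    count = 0
    total = 2 ** n
    for signs in itertools.product((0, 1), repeat=n):
        w = float(sum(r for r, s in zip(ranks, signs) if s))
        if min(w, ranks.sum() - w) <= min(w_plus, ranks.sum() - w_plus):
            count += 1
    return count / total


def dvh_sort_oracle(dose_values, dose_bins):
    """V(>=D) by explicit counting."""
    dose_values = np.sort(np.asarray(dose_values, dtype=float))
    n = dose_values.size
    return np.array([np.sum(dose_values >= d) / n for d in dose_bins])
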
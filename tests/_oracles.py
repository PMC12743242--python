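"""Independent brute-force oracles shared across test modules."""

import itertools

import numpy as np


def brute_force_best_matching(detected, reference, half):
    """Maximum-cardinality, then minimum-total-error one-to-one matching by
    exhaustive enumeration (feasible for n <= 8)."""
    best = (0, 0.0)
    nd, nr = len(detected), len(reference)
    for k in range(min(nd, nr), -1, -1):
        found = None
        for ref_sub in itertools.combinations(range(nr), k):
            for det_sub in itertools.permutations(range(nd), k):
                errs = [abs(detected[d] - reference[r])
                        for r, d in zip(ref_sub, det_sub)]
                if all(e <= half for e in errs):
                    tot = sum(errs)
                    if found is None or tot < found:
                        found = tot
        if found is not None:
            best = (k, found)
            break
    return best


def icc21_anova_oracle(data):
    """ICC(2,1) from the two-way ANOVA mean squares, written out directly."""
    data = np.asarray(data, dtype=float)
    n, k = data.shape
    grand = data.mean()
    row_m = data.mean(axis=1)
    col_m = data.mean(axis=0)
    ss_rows = k * np.sum((row_m - grand) ** 2)
    ss_cols = n * np.sum((col_m - grand) ** 2)
    ss_total = np.sum((data - grand) ** 2)
    ss_err = ss_total - ss_rows - ss_cols
    msr = ss_rows / (n - 1)
    msc = ss_cols / (k - 1)
    mse = ss_err / ((n - 1) * (k - 1))
    return (msr - mse) / (msr + (k - 1) * mse + k * (msc - mse) / n)


def icc_consistency_oracle(data):
    """ICC(3,1) (consistency) for the shift-penalty comparison."""
    data = np.asarray(data, dtype=float)
    n, k = data.shape
    grand = data.mean()
    row_m = data.mean(axis=1)
    col_m = data.mean(axis=0)
    ss_rows = k * np.sum((row_m - grand) ** 2)
    ss_cols = n * np.sum((col_m - grand) ** 2)
    ss_err = np.sum((data - grand) ** 2) - ss_rows - ss_cols
    msr = ss_rows / (n - 1)
    mse = ss_err / ((n - 1) * (k - 1))
    return (msr - mse) / (msr + (k - 1) * mse)
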
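import numpy as np
import pandas as pd
import pytest

from asmnet.containers import ExpressionMatrix


def make_expression(case: np.ndarray, control: np.ndarray, gene_ids=None) -> ExpressionMatrix:
    """Build an ExpressionMatrix from per-condition value arrays (genes x samples)."""
    case = np.asarray(case, float)
    control = np.asarray(control, float)
    n_genes = case.shape[0]
    if gene_ids is None:
        gene_ids = [f"g{i}" for i in range(n_genes)]
    cols = [f"control_{i}" for i in range(control.shape[1])] + [f"case_{i}" for i in range(case.shape[1])]
    values = pd.DataFrame(np.hstack([control, case]), index=gene_ids, columns=cols)
    samples = pd.DataFrame(
        {"condition": ["control"] * control.shape[1] + ["case"] * case.shape[1]},
        index=pd.Index(cols, name="sample_id"),
    )
    return ExpressionMatrix(values=values, samples=samples)


def pcit_brute_force(R: np.ndarray) -> np.ndarray:
    """Naive O(n^3) PCIT: evaluate every trio with scalar arithmetic.

    Independent reference for the vectorized implementation; uses the same
    documented conventions (legs clipped to |r| <= 1 - 1e-12, zero-denominator
    ratio terms contribute 0, eps ratios via reciprocals).
    """
    R = np.asarray(R, float)
    n = R.shape[0]
    clip = 1.0 - 1e-12
    Rc = np.clip(R, -clip, clip)

    def inv(v: float) -> float:
        return 1.0 / v if v != 0.0 else 0.0

    keep = np.ones((n, n), dtype=bool)
    np.fill_diagonal(keep, False)
    for z in range(n):
        a = Rc[:, z]
        su = np.sqrt(1.0 - a * a)
        for x in range(n):
            if x == z:
                continue
            for y in range(n):
                if y == z or y == x:
                    continue
                rxy_z = (Rc[x, y] - a[x] * a[y]) / (su[x] * su[y])
                s_one_m = np.sqrt(1.0 - Rc[x, y] * Rc[x, y])
                rxz_y = (a[x] - Rc[x, y] * a[y]) / (s_one_m * su[y])
                ryz_x = (a[y] - Rc[x, y] * a[x]) / (s_one_m * su[x])
                eps = (rxy_z * inv(Rc[x, y]) + rxz_y * inv(a[x]) + ryz_x * inv(a[y])) / 3.0
                if abs(R[x, y]) < abs(eps * a[x]) and abs(R[x, y]) < abs(eps * a[y]):
                    keep[x, y] = False
                    keep[y, x] = False
    return keep


@pytest.fixture
def toy_counts():
    """Small hand-checkable count matrix (6 genes x 4 samples, 2 vs 2)."""
    from asmnet.containers import CountMatrix

    counts = pd.DataFrame(
        {
            "control_0": [100, 0, 40, 1, 800, 59],
            "control_1": [120, 0, 50, 0, 850, 80],
            "case_0": [10, 0, 45, 1, 900, 44],
            "case_1": [15, 0, 55, 2, 950, 78],
        },
        index=[f"g{i}" for i in range(6)],
    )
    samples = pd.DataFrame(
        {"condition": ["control", "control", "case", "case"]},
        index=pd.Index(counts.columns, name="sample_id"),
    )
    return CountMatrix(counts=counts, samples=samples)
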
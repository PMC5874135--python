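"""Covariate correction of brain scores and age-trajectory characterization.

Brain scores are first residualized on scanner field strength and sex
(multiple regression per latent variable, grand mean added back so corrected
scores stay on the original scale).  Corrected scores are then regressed on
age with polynomial models of degree 1-3; the degree is chosen by the
small-sample corrected Akaike criterion (AICc), and when the selected curve
has an interior maximum its location is reported as the peak age.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .pls import AgeGroupScheme, assign_groups


@dataclass
class CorrectionResult:
    """Covariate-corrected scores plus the fitted nuisance coefficients."""

    corrected: np.ndarray        # same shape as input scores
    coefficients: pd.DataFrame   # one row per (lv, covariate): coef, se
    dropped: tuple[str, ...]     # constant covariates removed


def correct_scores(scores, scanner_tesla, sex) -> CorrectionResult:
    """Residualize scores on scanner field strength and sex, per LV.

    The corrected score is the OLS residual of ``score ~ 1 + scanner + male``
    plus the grand mean; correcting twice is a no-op.  A constant covariate
    column is dropped with a warning instead of raising (it carries no
    information and would make the design singular).
    """
    scores = np.asarray(scores, dtype=float)
    one_d = scores.ndim == 1
    if one_d:
        scores = scores[:, None]
    n = scores.shape[0]
    scanner = np.asarray(scanner_tesla, dtype=float)
    male = np.asarray([1.0 if s in ("M", "m", 1, True) else 0.0 for s in np.asarray(sex)])
    if scanner.shape != (n,) or male.shape != (n,):
        raise ValueError("covariates must match the number of participants")

    cols, names, dropped = [], [], []
    for name, col in (("scanner_tesla", scanner), ("sex_male", male)):
        if np.ptp(col) == 0:
            dropped.append(name)
            warnings.warn(f"covariate {name!r} is constant; dropped", stacklevel=2)
        else:
            cols.append(col)
            names.append(name)

    if not cols:
        corrected = scores.copy()
        coefs = pd.DataFrame(columns=["lv", "covariate", "coef", "se"])
    else:
        design = sm.add_constant(np.column_stack(cols))
        corrected = np.empty_like(scores)
        rows = []
        for j in range(scores.shape[1]):
            fit = sm.OLS(scores[:, j], design).fit()
            corrected[:, j] = fit.resid + scores[:, j].mean()
            for name, coef, se in zip(names, fit.params[1:], fit.bse[1:]):
                rows.append({"lv": j + 1, "covariate": name, "coef": coef, "se": se})
        coefs = pd.DataFrame(rows)

    return CorrectionResult(
        corrected=corrected[:, 0] if one_d else corrected,
        coefficients=coefs,
        dropped=tuple(dropped),
    )


@dataclass
class TrajectoryFit:
    """Selected polynomial age model for one latent variable's scores.

    ``coefficients`` are in ascending powers of age (years, uncentered);
    ``peak_age`` is the location of an interior stationary maximum of the
    selected curve, or None when the curve is monotone or peaks at a boundary.
    """

    degree: int
    coefficients: np.ndarray
    aicc: float
    aicc_by_degree: dict[int, float]
    peak_age: float | None
    age_range: tuple[float, float]

    def predict(self, age):
        return np.polynomial.polynomial.polyval(np.asarray(age, float), self.coefficients)


def _aicc(rss: float, n: int, n_params: int) -> float:
    # Gaussian log-likelihood AIC with small-sample correction; n_params counts
    # the regression coefficients plus the noise variance.
    k = n_params + 1
    if n - k - 1 <= 0:
        return np.inf
    return n * np.log(max(rss, 1e-300) / n) + 2 * k + 2 * k * (k + 1) / (n - k - 1)


def _interior_maximum(coefs_centered: np.ndarray, lo: float, hi: float):
    """Location of the largest interior stationary maximum, if any."""
    deriv = np.polynomial.polynomial.polyder(coefs_centered)
    roots = np.polynomial.polynomial.polyroots(deriv)
    real = roots[np.abs(roots.imag) < 1e-9].real
    eps = 1e-9 * max(1.0, hi - lo)
    interior = real[(real > lo + eps) & (real < hi - eps)]
    if interior.size == 0:
        return None
    second = np.polynomial.polynomial.polyder(deriv)
    curv = np.polynomial.polynomial.polyval(interior, second)
    maxima = interior[curv < 0]
    if maxima.size == 0:
        return None
    vals = np.polynomial.polynomial.polyval(maxima, coefs_centered)
    best = maxima[int(np.argmax(vals))]
    # an interior stationary maximum must also beat the boundary values
    if np.max(vals) < max(
        np.polynomial.polynomial.polyval(lo, coefs_centered),
        np.polynomial.polynomial.polyval(hi, coefs_centered),
    ):
        return None
    return float(best)


def fit_trajectory(
    scores,
    ages,
    max_degree: int = 3,
    scheme: AgeGroupScheme | None = None,
) -> TrajectoryFit:
    """Fit polynomial age models of degree 1..max_degree, select by AICc.

    Requires at least 10 participants spanning at least 3 age groups.  Ages
    are centered and scaled internally for conditioning; reported coefficients
    are in natural (years) units.
    """
    scores = np.asarray(scores, dtype=float)
    ages = np.asarray(ages, dtype=float)
    if scores.shape != ages.shape:
        raise ValueError("scores and ages must be 1-D and aligned")
    n = ages.size
    if n < 10:
        raise ValueError(f"need at least 10 participants, got {n}")
    if np.ptp(ages) == 0:
        raise ValueError("degenerate design: all ages identical")
    n_groups = np.unique(assign_groups(ages, scheme)).size
    if n_groups < 3:
        raise ValueError(
            f"participants span only {n_groups} age group(s); need at least 3"
        )

    loc, scale = ages.mean(), ages.std()
    z = (ages - loc) / scale
    lo_z, hi_z = z.min(), z.max()

    tss = float(np.sum((scores - scores.mean()) ** 2))
    fits: dict[int, tuple[np.ndarray, float]] = {}
    aiccs: dict[int, float] = {}
    for deg in range(1, max_degree + 1):
        design = np.vander(z, deg + 1, increasing=True)
        coefs, *_ = np.linalg.lstsq(design, scores, rcond=None)
        rss = float(np.sum((scores - design @ coefs) ** 2))
        # floor the RSS at numerical-noise level so exact fits tie (and the
        # tie then resolves to the lowest degree)
        aiccs[deg] = _aicc(max(rss, 1e-12 * tss), n, deg + 1)
        fits[deg] = (coefs, rss)

    best_deg = min(aiccs, key=lambda d: (aiccs[d], d))
    coefs_z, _ = fits[best_deg]

    peak_z = _interior_maximum(coefs_z, lo_z, hi_z)
    peak_age = None if peak_z is None else float(peak_z * scale + loc)

    # convert coefficients from the standardized to the natural age scale:
    # p(z) with z=(a-loc)/scale  ->  q(a)
    basis = np.polynomial.polynomial.Polynomial([-loc / scale, 1.0 / scale])
    poly_nat = sum(
        c * basis**k for k, c in enumerate(coefs_z)
    )
    coefs_nat = np.zeros(best_deg + 1)
    conv = np.asarray(poly_nat.coef if hasattr(poly_nat, "coef") else [poly_nat])
    coefs_nat[: conv.size] = conv

    return TrajectoryFit(
        degree=best_deg,
        coefficients=coefs_nat,
        aicc=aiccs[best_deg],
        aicc_by_degree=aiccs,
        peak_age=peak_age,
        age_range=(float(ages.min()), float(ages.max())),
    )


def plot_trajectory(fit: TrajectoryFit, scores, ages, path, title: str = ""):
    """Scatter corrected scores against age with the fitted curve; save to path."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    ages = np.asarray(ages, dtype=float)
    fig, ax = plt.subplots(figsize=(5, 3.5))
    ax.scatter(ages, scores, s=8, alpha=0.5, color="#4878a8", label="corrected scores")
    grid = np.linspace(ages.min(), ages.max(), 200)
    ax.plot(grid, fit.predict(grid), color="#b24040",
            label=f"degree {fit.degree} fit")
    if fit.peak_age is not None:
        ax.axvline(fit.peak_age, color="#b24040", ls="--", lw=0.8,
                   label=f"peak at {fit.peak_age:.1f} y")
    ax.set_xlabel("age (years)")
    ax.set_ylabel("brain score")
    if title:
        ax.set_title(title)
    ax.legend(fontsize=7)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
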
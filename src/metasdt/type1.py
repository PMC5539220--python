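"""Type-1 signal-detection estimation from rating-count tables.

Equal-variance model: sensitivity ``d' = z(H) - z(F)`` and criterion
``c = -(z(H) + z(F)) / 2`` from the 2x2 collapse of the rating table.

Unequal-variance model: the zROC (both cumulative-rating ROC coordinates
z-transformed) is linear under Gaussian evidence with unequal spread; its
slope ``s`` is the S1-to-S2 evidence-SD ratio, estimated here by ordinary
least squares over the 2K-1 rating criteria.  Sensitivity is then

    da = sqrt(2 / (1 + s^2)) * (z(H) - s * z(F))

evaluated at the type-1 decision criterion, which reduces to d' when s = 1.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.stats import norm

from .tables import S1, S2, RatingTable, pad_counts

__all__ = ["Type1SDT", "Type1Results", "fit_type1_equal", "fit_type1_unequal"]


@dataclass(frozen=True)
class Type1Results:
    """Type-1 sensitivity/criterion estimates for one rating table."""

    d_prime: float
    criterion_c: float
    hit_rate: float
    fa_rate: float
    s: float
    da: float
    variance_model: str
    padding_applied: bool
    n_trials: float
    zroc_points: np.ndarray | None = field(default=None, repr=False)
    zroc_intercept: float | None = None

    @property
    def relative_criterion(self) -> float:
        """c' = c/d' — criterion position in units of sensitivity.

        Carried into the type-2 model, where the meta-level criterion is
        held at the same relative position.  Zero-d' tables fall back to
        the raw criterion sign convention (c' undefined; returns nan).
        """
        if self.d_prime == 0:
            return float("nan")
        return self.criterion_c / self.d_prime

    def summary(self) -> str:
        lines = [
            f"Type-1 SDT fit ({self.variance_model} variance)",
            "=" * 44,
            f"  trials            {self.n_trials:10.1f}",
            f"  hit rate          {self.hit_rate:10.4f}",
            f"  false-alarm rate  {self.fa_rate:10.4f}",
            f"  d'                {self.d_prime:10.4f}",
            f"  criterion c       {self.criterion_c:10.4f}",
            f"  zROC slope s      {self.s:10.4f}",
            f"  da                {self.da:10.4f}",
            f"  padding applied   {str(self.padding_applied):>10}",
        ]
        return "\n".join(lines)

    def plot_zroc(self, ax=None):
        """Diagnostic zROC scatter with the fitted line (unequal fits)."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        if self.zroc_points is not None:
            zf, zh = self.zroc_points.T
            ax.plot(zf, zh, "o", label="rating criteria")
            grid = np.linspace(zf.min(), zf.max(), 50)
            ax.plot(grid, self.zroc_intercept + self.s * grid, "-",
                    label=f"slope s = {self.s:.3f}")
        ax.set_xlabel("z(false-alarm rate)")
        ax.set_ylabel("z(hit rate)")
        ax.legend()
        return ax


class Type1SDT:
    """Type-1 SDT model for one rating table.

    Parameters
    ----------
    table : RatingTable
        Raw or padded counts; zero cells are padded on construction
        according to `padding` (recorded in the results).
    variance : {"equal", "unequal"}
        Equal-variance d'/c, or unequal-variance da with zROC slope s.
    padding : str
        Scheme passed to :func:`metasdt.tables.pad_counts`.
    """

    def __init__(self, table: RatingTable, variance: str = "equal",
                 padding: str = "only-if-needed"):
        if variance not in ("equal", "unequal"):
            raise ValueError(f"unknown variance model {variance!r}")
        if variance == "unequal" and table.n_levels < 3:
            raise ValueError("unequal-variance fit needs K >= 3 confidence levels")
        self.variance = variance
        self.table = pad_counts(table, scheme=padding)

    # -- internals ---------------------------------------------------------

    def _rates_2x2(self) -> tuple[float, float]:
        tab = self.table.choice_table()
        hit = tab[S2, S2] / tab[S2].sum()
        fa = tab[S1, S2] / tab[S1].sum()
        if not (0 < hit < 1 and 0 < fa < 1):
            raise RuntimeError(
                "hit/FA rate at 0 or 1 after padding; padding contract broken")
        return float(hit), float(fa)

    def _zroc(self) -> np.ndarray:
        """(z(F), z(H)) for every usable interior rating criterion."""
        fa = self.table.cumulative_rates(S1)
        hit = self.table.cumulative_rates(S2)
        usable = (fa > 0) & (fa < 1) & (hit > 0) & (hit < 1)
        pts = np.column_stack([norm.ppf(fa[usable]), norm.ppf(hit[usable])])
        # collapse numerically identical points before counting them
        distinct = np.unique(np.round(pts, 12), axis=0)
        if len(distinct) < 2:
            raise ValueError("degenerate ROC: fewer than 2 distinct usable points")
        return pts

    def fit(self) -> Type1Results:
        hit, fa = self._rates_2x2()
        zh, zf = norm.ppf(hit), norm.ppf(fa)
        d_prime = zh - zf
        c = -0.5 * (zh + zf)

        if self.variance == "equal":
            s, da, pts, intercept = 1.0, d_prime, None, None
        else:
            pts = self._zroc()
            zf_pts, zh_pts = pts[:, 0], pts[:, 1]
            s, intercept = np.polyfit(zf_pts, zh_pts, 1)
            if s <= 0:
                raise ValueError(f"non-positive fitted zROC slope ({s:.3f}); "
                                 "rating data inconsistent with a Gaussian ROC")
            da = np.sqrt(2.0 / (1.0 + s**2)) * (zh - s * zf)

        return Type1Results(
            d_prime=float(d_prime), criterion_c=float(c),
            hit_rate=hit, fa_rate=fa, s=float(s), da=float(da),
            variance_model=self.variance,
            padding_applied=self.table.padding_applied,
            n_trials=self.table.n_trials,
            zroc_points=pts, zroc_intercept=None if intercept is None else float(intercept),
        )


def fit_type1_equal(table: RatingTable, padding: str = "only-if-needed") -> Type1Results:
    """Equal-variance d' and criterion c from a rating table."""
    return Type1SDT(table, variance="equal", padding=padding).fit()


def fit_type1_unequal(table: RatingTable, padding: str = "only-if-needed") -> Type1Results:
    """Unequal-variance da and zROC slope s from a rating table."""
    return Type1SDT(table, variance="unequal", padding=padding).fit()
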
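"""Two-way repeated-measures ANOVA for behavioral time-bin designs.

Two designs occur in dyadic cohabitation analyses and both are supported by
:class:`RepeatedMeasuresAnova`:

* **fully within** — e.g. sex (2 levels, within dyad) × time bin (within),
  with the dyad as the subject unit.  With n subjects, a levels of the first
  factor and b bins, the uncorrected df are: first factor
  (a−1, (a−1)(n−1)); time (b−1, (b−1)(n−1)); interaction
  ((a−1)(b−1), (a−1)(b−1)(n−1)).
* **mixed** — e.g. dyad type (between subjects) × time bin (within).  With
  N subjects in g groups: group (g−1, N−g); time (b−1, (b−1)(N−g));
  interaction ((g−1)(b−1), (b−1)(N−g)).

Each effect is tested against its own error term (factor × subject
interaction, or subject-within-group / bin × subject-within-group).  No
sphericity correction is applied by default so that the printed df follow
the closed forms above; a Greenhouse–Geisser option adjusts the p value
only.  Subjects with incomplete cells are dropped listwise and logged.
Zero error variance is reported as a flagged degenerate effect (F = NaN)
rather than an exception.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)


class InsufficientDataError(ValueError):
    """Fewer than 2 subjects per cell."""


@dataclass
class AnovaResults:
    """Fitted ANOVA: effect table plus design metadata.

    ``table`` has one row per effect with columns
    ``effect, df_num, df_den, F, p, degenerate``.
    """

    table: pd.DataFrame
    design: str
    n_subjects: int
    dropped_subjects: list = field(default_factory=list)
    posthoc: pd.DataFrame | None = None

    def effect(self, name: str) -> pd.Series:
        row = self.table[self.table["effect"] == name]
        if row.empty:
            raise KeyError(name)
        return row.iloc[0]

    def summary(self) -> str:
        lines = [
            f"Two-way repeated-measures ANOVA ({self.design} design, "
            f"n={self.n_subjects} subjects)"
        ]
        if self.dropped_subjects:
            lines.append(f"dropped (incomplete): {self.dropped_subjects}")
        lines.append(f"{'effect':<16}{'df':>12}{'F':>10}{'P':>10}")
        for _, r in self.table.iterrows():
            fstr = "nan" if np.isnan(r.F) else f"{r.F:.2f}"
            pstr = "nan" if np.isnan(r.p) else f"{r.p:.3g}"
            flag = "  (degenerate)" if r.degenerate else ""
            lines.append(
                f"{r.effect:<16}{f'{r.df_num}, {r.df_den}':>12}{fstr:>10}{pstr:>10}{flag}"
            )
        return "\n".join(lines)

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False)


def _f_p(ss_eff, df_eff, ss_err, df_err):
    from scipy import stats

    if df_err <= 0 or ss_err <= 1e-12 * max(ss_eff, 1.0):
        return np.nan, np.nan, True
    F = (ss_eff / df_eff) / (ss_err / df_err)
    p = float(stats.f.sf(F, df_eff, df_err))
    return float(F), p, False


class RepeatedMeasuresAnova:
    """Model object for the two supported repeated-measures designs.

    Parameters
    ----------
    data : DataFrame
        Long format, one row per (subject, bin[, factor]) observation.
    dv : str
        Dependent-variable column.
    subject : str
        Subject-identifier column (the dyad for within-within designs).
    within : str
        Repeated-measure column (time bin or behavior pair).
    factor : str, optional
        Second *within-subject* factor (e.g. sex) → fully-within design.
    between : str, optional
        Between-subject factor (e.g. dyad type) → mixed design.

    Exactly one of ``factor`` / ``between`` must be given.
    """

    def __init__(self, data, dv, subject, within, factor=None, between=None):
        if (factor is None) == (between is None):
            raise ValueError("give exactly one of factor= (within) or between=")
        self.data = data
        self.dv = dv
        self.subject = subject
        self.within = within
        self.factor = factor
        self.between = between
        self.design = "within-within" if factor is not None else "mixed"

    # -- fitting ----------------------------------------------------------

    def fit(self, gg_correction: bool = False) -> AnovaResults:
        if self.design == "within-within":
            return self._fit_within_within(gg_correction)
        return self._fit_mixed(gg_correction)

    def _complete_cube(self, index_cols):
        """Pivot to subjects × cells, dropping incomplete subjects listwise."""
        wide = self.data.pivot_table(
            index=self.subject, columns=index_cols, values=self.dv, aggfunc="mean"
        )
        incomplete = wide.index[wide.isna().any(axis=1)].tolist()
        if incomplete:
            logger.info("dropping incomplete subjects: %s", incomplete)
        wide = wide.dropna(axis=0)
        return wide, incomplete

    def _fit_within_within(self, gg_correction) -> AnovaResults:
        wide, dropped = self._complete_cube([self.factor, self.within])
        a = wide.columns.get_level_values(0).nunique()
        b = wide.columns.get_level_values(1).nunique()
        n = len(wide)
        if n < 2:
            raise InsufficientDataError("need >= 2 complete subjects")
        Y = wide.to_numpy().reshape(n, a, b)
        g = Y.mean()
        m_s = Y.mean(axis=(1, 2))
        m_a = Y.mean(axis=(0, 2))
        m_b = Y.mean(axis=(0, 1))
        m_sa = Y.mean(axis=2)
        m_sb = Y.mean(axis=1)
        m_ab = Y.mean(axis=0)

        ss_a = n * b * np.sum((m_a - g) ** 2)
        ss_b = n * a * np.sum((m_b - g) ** 2)
        ss_ab = n * np.sum((m_ab - m_a[:, None] - m_b[None, :] + g) ** 2)
        ss_as = b * np.sum((m_sa - m_s[:, None] - m_a[None, :] + g) ** 2)
        ss_bs = a * np.sum((m_sb - m_s[:, None] - m_b[None, :] + g) ** 2)
        ss_total = np.sum((Y - g) ** 2)
        ss_s = a * b * np.sum((m_s - g) ** 2)
        ss_abs = ss_total - ss_a - ss_b - ss_ab - ss_s - ss_as - ss_bs
        ss_abs = max(ss_abs, 0.0)

        rows = []
        for name, ss_e, df_e, ss_r, df_r in (
            (self.factor, ss_a, a - 1, ss_as, (a - 1) * (n - 1)),
            (self.within, ss_b, b - 1, ss_bs, (b - 1) * (n - 1)),
            ("interaction", ss_ab, (a - 1) * (b - 1), ss_abs, (a - 1) * (b - 1) * (n - 1)),
        ):
            F, p, degen = _f_p(ss_e, df_e, ss_r, df_r)
            rows.append((name, df_e, df_r, F, p, degen))
        table = pd.DataFrame(
            rows, columns=["effect", "df_num", "df_den", "F", "p", "degenerate"]
        )
        if gg_correction:
            table = self._apply_gg(table, wide, b)
        return AnovaResults(table, self.design, n, dropped)

    def _fit_mixed(self, gg_correction) -> AnovaResults:
        df = self.data
        groups = df.groupby(self.between)[self.subject].nunique()
        if (groups < 2).any():
            raise InsufficientDataError("need >= 2 subjects per group")
        wide, dropped = self._complete_cube([self.within])
        grp_of = (
            df.drop_duplicates(self.subject)
            .set_index(self.subject)[self.between]
            .loc[wide.index]
        )
        b = wide.shape[1]
        N = len(wide)
        Y = wide.to_numpy()
        glabels = grp_of.to_numpy()
        unique_g = pd.unique(glabels)
        g_count = len(unique_g)
        if N - g_count < 1:
            raise InsufficientDataError("need more subjects than groups")

        grand = Y.mean()
        m_s = Y.mean(axis=1)
        m_j = Y.mean(axis=0)
        ss_total = np.sum((Y - grand) ** 2)
        ss_subj = b * np.sum((m_s - grand) ** 2)

        ss_g = 0.0
        ss_gb = 0.0
        for gl in unique_g:
            sel = glabels == gl
            nk = sel.sum()
            mk = Y[sel].mean()
            ss_g += b * nk * (mk - grand) ** 2
            m_kj = Y[sel].mean(axis=0)
            ss_gb += nk * np.sum((m_kj - mk - m_j + grand) ** 2)
        ss_sg = ss_subj - ss_g
        ss_b = N * np.sum((m_j - grand) ** 2)
        ss_bsg = ss_total - ss_subj - ss_b - ss_gb
        ss_bsg = max(ss_bsg, 0.0)

        rows = []
        for name, ss_e, df_e, ss_r, df_r in (
            (self.between, ss_g, g_count - 1, ss_sg, N - g_count),
            (self.within, ss_b, b - 1, ss_bsg, (b - 1) * (N - g_count)),
            (
                "interaction",
                ss_gb,
                (g_count - 1) * (b - 1),
                ss_bsg,
                (b - 1) * (N - g_count),
            ),
        ):
            F, p, degen = _f_p(ss_e, df_e, ss_r, df_r)
            rows.append((name, df_e, df_r, F, p, degen))
        table = pd.DataFrame(
            rows, columns=["effect", "df_num", "df_den", "F", "p", "degenerate"]
        )
        if gg_correction:
            table = self._apply_gg(table, wide, b)
        return AnovaResults(table, self.design, N, dropped)

    @staticmethod
    def _apply_gg(table: pd.DataFrame, wide: pd.DataFrame, b: int) -> pd.DataFrame:
        """Greenhouse–Geisser epsilon on the within covariance; p adjusted only."""
        from scipy import stats

        if b < 3:
            return table
        if isinstance(wide.columns, pd.MultiIndex):
            V = np.cov(
                wide.T.groupby(level=1).mean().to_numpy()
            )
        else:
            V = np.cov(wide.to_numpy().T)
        k = V.shape[0]
        mean_diag = np.trace(V) / k
        num = (k * (mean_diag - V.mean())) ** 2
        den = (k - 1) * (np.sum(V**2) - 2 * k * np.sum(V.mean(axis=1) ** 2) + k**2 * V.mean() ** 2)
        eps = num / den if den > 0 else 1.0
        eps = min(max(eps, 1.0 / (k - 1)), 1.0)
        out = table.copy()
        out["p_gg"] = out["p"]
        for i, r in out.iterrows():
            if r.effect == "interaction" or r.df_num >= k - 1:
                if not np.isnan(r.F):
                    out.at[i, "p_gg"] = float(
                        stats.f.sf(r.F, r.df_num * eps, r.df_den * eps)
                    )
        out.attrs["gg_epsilon"] = float(eps)
        return out
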
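"""Two-group differential editing: binomial GLM + LRT, gated Fisher's exact
test, Benjamini-Hochberg FDR, and DRE calling.

The GLM is a binomial regression with logit link on per-sample (alt, ref)
counts, logit(pi_i) = b0 + b1*group_i.  Because group is the only covariate
the maximum-likelihood fit is available in closed form (the pooled per-group
proportions), so the likelihood-ratio statistic

    LRT = 2 * (ll_full - ll_null)  ~  chi2(1)

is computed analytically; separation (a group with all-zero or all-total alt
counts) is handled naturally by the boundary likelihood with 0*log(0) = 0.
An optional group-label permutation mode replaces the chi-squared p-value
with an empirical one, and a quasi-binomial option rescales the statistic by
the Pearson dispersion of the full model.

Fisher's exact test compares the pooled 2x2 table of (alt, ref) per group and
is run only for sites with GLM p < 0.05; BH adjustment is applied separately
to the GLM p-values (all tested sites) and the Fisher p-values (gated sites).
A site is differentially edited (DRE) when GLM FDR < 0.2 or Fisher FDR < 0.2.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .io import SampleSheet


@dataclass(frozen=True)
class TestConfig:
    __test__ = False  # not a pytest class, despite the name

    glm_gate_p: float = 0.05
    dre_fdr: float = 0.2
    fdr_method: str = "fdr_bh"
    permutations: int = 0
    overdispersion: bool = False
    # The GLM gate is a selection step: by default the Fisher BH family is the
    # full tested set, with unselected sites entered at p = 1, so that the
    # Fisher FDR remains interpretable after selection.  Setting this False
    # adjusts the gated p-values alone.
    selection_adjusted_fisher: bool = True

    def __post_init__(self):
        if not (0 < self.glm_gate_p < 1 and 0 < self.dre_fdr < 1):
            raise ValueError("thresholds must be in (0,1)")


# ---------------------------------------------------------------------------
# binomial log-likelihood pieces (0*log(0) = 0 at the boundary)

def _binom_ll(k, n, p):
    k = np.asarray(k, dtype=float)
    n = np.asarray(n, dtype=float)
    p = np.asarray(p, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        t1 = np.where(k > 0, k * np.log(p), 0.0)
        t2 = np.where(n - k > 0, (n - k) * np.log1p(-p), 0.0)
    return t1 + t2


def lrt_statistic(alt, depth, group2) -> np.ndarray:
    """Vectorised LRT statistics.

    alt, depth: arrays of shape (n_sites, n_samples); group2: boolean mask of
    samples in the second group.
    """
    alt = np.atleast_2d(np.asarray(alt, dtype=float))
    depth = np.atleast_2d(np.asarray(depth, dtype=float))
    g2 = np.asarray(group2, dtype=bool)
    k1, n1 = alt[:, ~g2].sum(1), depth[:, ~g2].sum(1)
    k2, n2 = alt[:, g2].sum(1), depth[:, g2].sum(1)
    with np.errstate(invalid="ignore", divide="ignore"):
        p1 = np.where(n1 > 0, k1 / np.maximum(n1, 1), 0.0)
        p2 = np.where(n2 > 0, k2 / np.maximum(n2, 1), 0.0)
        p0 = (k1 + k2) / np.maximum(n1 + n2, 1)
    ll_full = _binom_ll(k1, n1, p1) + _binom_ll(k2, n2, p2)
    ll_null = _binom_ll(k1, n1, p0) + _binom_ll(k2, n2, p0)
    return np.maximum(2.0 * (ll_full - ll_null), 0.0)


def glm_lrt_test(alt, depth, group2, permutations: int = 0,
                 rng: np.random.Generator | None = None,
                 overdispersion: bool = False) -> tuple[float, float]:
    """(LRT statistic, p-value) for one site.

    Requires >= 2 samples per group.  Returns (nan, nan) when either group
    has zero total depth (site untestable).  With ``permutations`` > 0 the
    p-value is the empirical tail probability over group-label permutations.
    """
    alt = np.asarray(alt, dtype=float)
    depth = np.asarray(depth, dtype=float)
    g2 = np.asarray(group2, dtype=bool)
    if (~g2).sum() < 2 or g2.sum() < 2:
        raise ValueError("need >= 2 samples per group")
    if depth[~g2].sum() == 0 or depth[g2].sum() == 0:
        return float("nan"), float("nan")
    stat = float(lrt_statistic(alt[None, :], depth[None, :], g2)[0])
    scale = 1.0
    if overdispersion:
        scale = _pearson_dispersion(alt, depth, g2)
        stat = stat / scale
    if permutations > 0:
        rng = rng or np.random.default_rng()
        n = len(alt)
        hits = 0
        for _ in range(permutations):
            perm = rng.permutation(n)
            s = lrt_statistic(alt[None, perm], depth[None, perm], g2)[0] / scale
            if s >= stat - 1e-12:
                hits += 1
        return stat, (1.0 + hits) / (1.0 + permutations)
    return stat, float(stats.chi2.sf(stat, df=1))


def _pearson_dispersion(alt, depth, g2) -> float:
    ok = depth > 0
    p_hat = np.empty(len(alt))
    for mask in (~g2, g2):
        m = mask & ok
        p_hat[mask] = alt[m].sum() / max(depth[m].sum(), 1.0)
    mu = depth * p_hat
    var = depth * p_hat * (1 - p_hat)
    resid2 = np.where(var > 0, (alt - mu) ** 2 / np.maximum(var, 1e-300), 0.0)
    dof = max(int(ok.sum()) - 2, 1)
    return max(float(resid2[ok].sum()) / dof, 1e-8)


def fisher_pooled_test(alt, depth, group2) -> float:
    """Two-sided Fisher's exact p on the pooled per-group (alt, ref) table."""
    alt = np.asarray(alt)
    depth = np.asarray(depth)
    g2 = np.asarray(group2, dtype=bool)
    a1, n1 = int(alt[~g2].sum()), int(depth[~g2].sum())
    a2, n2 = int(alt[g2].sum()), int(depth[g2].sum())
    table = [[a1, n1 - a1], [a2, n2 - a2]]
    if min(a1 + a2, (n1 - a1) + (n2 - a2)) == 0 or min(n1, n2) == 0:
        return 1.0
    return float(stats.fisher_exact(table, alternative="two-sided")[1])


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up FDR; NaNs are excluded and re-inserted."""
    p = np.asarray(pvalues, dtype=float)
    out = np.full(p.shape, np.nan)
    ok = ~np.isnan(p)
    if ok.sum():
        out[ok] = multipletests(p[ok], method="fdr_bh")[1]
    return out


# ---------------------------------------------------------------------------
# site-level driver

def run_differential(levels_alt: np.ndarray, levels_ref: np.ndarray,
                     samples: list[str], sheet: SampleSheet,
                     site_ids: list[str],
                     config: TestConfig = TestConfig(),
                     rng: np.random.Generator | None = None) -> pd.DataFrame:
    """Differential table over sites.

    ``levels_alt``/``levels_ref``: (n_sites, n_samples) coding-strand alt and
    ref counts, sample columns ordered as ``samples``.  The second group label
    (sorted order) is the "case" group; delta = mean case level - mean
    control level.
    """
    sheet.require_min_per_group(2)
    g2 = np.array([sheet.groups[s] == sheet.labels[1] for s in samples])
    alt = np.asarray(levels_alt, dtype=float)
    ref = np.asarray(levels_ref, dtype=float)
    depth = alt + ref
    n_sites = alt.shape[0]

    stats_, glm_p = np.full(n_sites, np.nan), np.full(n_sites, np.nan)
    for i in range(n_sites):
        if depth[i, ~g2].sum() == 0 or depth[i, g2].sum() == 0:
            continue  # one group uncovered: test skipped, p missing
        stats_[i], glm_p[i] = glm_lrt_test(
            alt[i], depth[i], g2, permutations=config.permutations, rng=rng,
            overdispersion=config.overdispersion)
    glm_fdr = bh_adjust(glm_p)

    fisher_p = np.full(n_sites, np.nan)
    gate = glm_p < config.glm_gate_p
    for i in np.nonzero(gate)[0]:
        fisher_p[i] = fisher_pooled_test(alt[i], depth[i], g2)
    if config.selection_adjusted_fisher:
        family = np.where(gate, fisher_p, np.where(np.isnan(glm_p), np.nan, 1.0))
        fisher_fdr = np.where(gate, bh_adjust(family), np.nan)
    else:
        fisher_fdr = bh_adjust(fisher_p)

    with np.errstate(invalid="ignore", divide="ignore"):
        lv = np.where(depth > 0, alt / np.maximum(depth, 1), np.nan)
    mean_case = np.nanmean(np.where(g2, lv, np.nan), axis=1)
    mean_ctrl = np.nanmean(np.where(~g2, lv, np.nan), axis=1)
    delta = mean_case - mean_ctrl

    df = pd.DataFrame({
        "site": site_ids,
        "lrt_stat": stats_,
        "glm_p": glm_p, "glm_fdr": glm_fdr,
        "fisher_p": fisher_p, "fisher_fdr": fisher_fdr,
        f"mean_level_{sheet.labels[1]}": mean_case,
        f"mean_level_{sheet.labels[0]}": mean_ctrl,
        "delta": delta,
    })
    return call_dre(df, config)


def call_dre(df: pd.DataFrame, config: TestConfig = TestConfig()) -> pd.DataFrame:
    """Add is_dre and direction columns per the DRE definition
    (GLM FDR < 0.2 or Fisher FDR < 0.2; tie in delta -> direction 'none')."""
    df = df.copy()
    glm_hit = df["glm_fdr"] < config.dre_fdr
    fisher_hit = df["fisher_fdr"] < config.dre_fdr
    df["is_dre"] = (glm_hit.fillna(False) | fisher_hit.fillna(False))
    delta = df["delta"]
    df["direction"] = np.select(
        [delta > 0, delta < 0], ["up", "down"], default="none")
    return df


def dre_gene_sets(df: pd.DataFrame, site_genes: dict[str, tuple[str, ...]]
                  ) -> dict[str, set]:
    """Distinct host genes of DRE sites, overall and by direction."""
    out = {"all": set(), "up": set(), "down": set()}
    for _, row in df[df["is_dre"]].iterrows():
        genes = site_genes.get(row["site"], ())
        out["all"].update(genes)
        if row["direction"] in ("up", "down"):
            out[row["direction"]].update(genes)
    return out
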
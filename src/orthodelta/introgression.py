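"""The Δ minor-topology asymmetry test for introgression.

Under the multispecies coalescent without gene flow, incomplete lineage
sorting produces the two minor (discordant) topologies around a species-tree
branch in equal expected numbers.  Introgression inflates one of them.  With
``DF1`` the more common and ``DF2`` the less common minor topology, the test
statistic is::

    Delta = (n_DF1 - n_DF2) / (n_DF1 + n_DF2)

which is 0 in expectation without introgression and positive otherwise.
Significance is assessed by bootstrap: gene trees are resampled with
replacement (default 2,000 replicates), the Δ of each replicate — with the
DF1/DF2 identities fixed at their observed values, so replicate values are
signed — gives a spread whose standard deviation yields a Z-score for the
observed Δ and a two-sided normal p-value.  Branches are only tested when
more than ``min_discordance`` (default 5%) of the decisive gene trees are
discordant, and the family-wise level is controlled across the tested
branches with the Dunn–Šidák correction.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats

from skbio import TreeNode

from ._util import derive_rng
from .concordance import (
    BranchConcordance,
    Classification,
    classification_matrix,
    discordant_fraction,
)
from .treeio import SpeciesMap

__all__ = [
    "TestConfig",
    "DeltaResult",
    "delta_statistic",
    "bootstrap_delta",
    "bootstrap_delta_counts",
    "sidak_threshold",
    "test_introgression",
    "results_to_dataframe",
    "results_to_json",
]


@dataclass
class TestConfig:
    """Parameters of the Δ test.

    ``n_bootstrap``     number of gene-tree resampling replicates.
    ``alpha``           family-wise significance level.
    ``min_discordance`` branch gate: test only branches where more than this
                        fraction of decisive trees is discordant.
    ``seed``            master seed; per-branch substreams are derived from
                        (seed, branch id).
    ``p_method``        "normal" (Z against the standard normal) or
                        "percentile" (two-sided bootstrap tail).
    ``reidentify_df1``  re-identify DF1 within each bootstrap replicate
                        (folds the null distribution; off by default).
    """

    n_bootstrap: int = 2000
    alpha: float = 0.05
    min_discordance: float = 0.05
    seed: int = 0
    p_method: str = "normal"
    reidentify_df1: bool = False

    def __post_init__(self) -> None:
        if self.n_bootstrap < 1:
            raise ValueError("n_bootstrap must be >= 1")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")
        if not 0 <= self.min_discordance < 1:
            raise ValueError("min_discordance must be in [0, 1)")
        if self.p_method not in ("normal", "percentile"):
            raise ValueError("p_method must be 'normal' or 'percentile'")


@dataclass
class DeltaResult:
    """Per-branch outcome of the Δ test (untested branches carry NaNs)."""

    branch_id: str
    n_concordant: int
    n_df1: int
    n_df2: int
    delta: float
    sd_boot: float
    z: float
    p: float
    alpha_adjusted: float
    significant: bool
    tested: bool


# ---------------------------------------------------------------------------
# Statistic
# ---------------------------------------------------------------------------

def delta_statistic(n_df1: int, n_df2: int) -> float:
    """Δ = (nDF1 − nDF2)/(nDF1 + nDF2), reordering so nDF1 >= nDF2."""
    if n_df1 < n_df2:
        n_df1, n_df2 = n_df2, n_df1
    total = n_df1 + n_df2
    if total == 0:
        raise ValueError("delta undefined: no discordant trees")
    return (n_df1 - n_df2) / total


def sidak_threshold(m: int, alpha: float) -> float:
    """Dunn–Šidák per-test level 1 − (1 − alpha)^(1/m) for m tests."""
    if m < 1:
        raise ValueError("number of tests must be >= 1")
    return 1.0 - (1.0 - alpha) ** (1.0 / m)


# ---------------------------------------------------------------------------
# Bootstrap
# ---------------------------------------------------------------------------

def bootstrap_delta_counts(
    counts: tuple[int, int, int, int],
    cfg: TestConfig,
    rng: np.random.Generator,
) -> tuple[float, float, float, float]:
    """Bootstrap Δ from branch tallies (concordant, alt1, alt2, paraphyletic).

    Resampling n gene trees with replacement from the observed label list is
    a multinomial draw over the label classes, which is how the replicates
    are generated here.  Returns (delta_obs, sd_boot, z, p).
    """
    n_conc, n_alt1, n_alt2, n_para = counts
    if n_alt1 + n_alt2 == 0:
        raise ValueError("bootstrap requires at least one discordant tree")
    df1_is_alt1 = n_alt1 >= n_alt2
    n_df1, n_df2 = (n_alt1, n_alt2) if df1_is_alt1 else (n_alt2, n_alt1)
    delta_obs = (n_df1 - n_df2) / (n_df1 + n_df2)

    vec = np.array([n_conc, n_alt1, n_alt2, n_para], dtype=float)
    n_total = int(vec.sum())
    draws = rng.multinomial(n_total, vec / n_total, size=cfg.n_bootstrap)
    x1 = draws[:, 1] if df1_is_alt1 else draws[:, 2]
    x2 = draws[:, 2] if df1_is_alt1 else draws[:, 1]
    if cfg.reidentify_df1:
        x1, x2 = np.maximum(x1, x2), np.minimum(x1, x2)
    denom = x1 + x2
    with np.errstate(invalid="ignore", divide="ignore"):
        deltas = np.where(denom > 0, (x1 - x2) / np.where(denom > 0, denom, 1), 0.0)
    sd = float(np.std(deltas, ddof=1)) if cfg.n_bootstrap > 1 else 0.0
    if sd == 0.0:
        warnings.warn(
            "degenerate bootstrap null (sd = 0); reporting p = 1",
            stacklevel=2,
        )
        return delta_obs, 0.0, math.nan, 1.0
    z = delta_obs / sd
    if cfg.p_method == "percentile":
        # two-sided tail of the centered bootstrap distribution
        centered = np.abs(deltas - deltas.mean())
        p = max(
            float(np.mean(centered >= abs(delta_obs))), 1.0 / cfg.n_bootstrap
        )
    else:
        p = float(2.0 * stats.norm.sf(abs(z)))
        p = max(p, 5e-324)
    return delta_obs, sd, z, min(p, 1.0)


def bootstrap_delta(
    labels: list[Classification], cfg: TestConfig, branch_id: str = "b"
) -> tuple[float, float, float, float]:
    """Bootstrap Δ from one branch's per-gene-tree classifications.

    Non-decisive labels are ignored; the full decisive list (concordant,
    minor and paraphyletic trees) is resampled, so the discordant count
    varies across replicates as it would under gene-tree resampling.
    """
    counts = [0, 0, 0, 0]
    order = (
        Classification.CONCORDANT,
        Classification.ALT1,
        Classification.ALT2,
        Classification.PARAPHYLETIC,
    )
    for lab in labels:
        if lab is Classification.NOT_DECISIVE:
            continue
        counts[order.index(lab)] += 1
    rng = derive_rng(cfg.seed, "delta-bootstrap", branch_id)
    return bootstrap_delta_counts(tuple(counts), cfg, rng)


# ---------------------------------------------------------------------------
# Full test
# ---------------------------------------------------------------------------

def test_introgression(
    gtrees: list[TreeNode],
    smap: SpeciesMap,
    stree: TreeNode,
    cfg: TestConfig,
) -> list[DeltaResult]:
    """Run the Δ test over every internal branch of the species tree.

    Every gene tree is classified at every branch; branches with a
    discordant fraction above ``cfg.min_discordance`` are tested, with the
    Šidák correction computed over the number of tested branches.  The
    report contains one row per internal branch, tested or not.
    """
    quads, labels = classification_matrix(gtrees, smap, stree)
    tallies = []
    for quad, row in zip(quads, labels):
        bc = BranchConcordance(branch_id=quad.branch_id, quad=quad)
        for lab in row:
            if lab is Classification.CONCORDANT:
                bc.n_concordant += 1
            elif lab is Classification.ALT1:
                bc.n_alt1 += 1
            elif lab is Classification.ALT2:
                bc.n_alt2 += 1
            elif lab is Classification.PARAPHYLETIC:
                bc.n_paraphyletic += 1
        tallies.append(bc)

    gated = []
    for bc in tallies:
        ok = (
            bc.n_decisive > 0
            and (bc.n_alt1 + bc.n_alt2) > 0
            and discordant_fraction(bc) > cfg.min_discordance
        )
        gated.append(ok)
    m = sum(gated)
    alpha_adj = sidak_threshold(m, cfg.alpha) if m else math.nan

    results = []
    for bc, ok in zip(tallies, gated):
        n_df1 = max(bc.n_alt1, bc.n_alt2)
        n_df2 = min(bc.n_alt1, bc.n_alt2)
        if not ok:
            results.append(
                DeltaResult(
                    branch_id=bc.branch_id,
                    n_concordant=bc.n_concordant,
                    n_df1=n_df1,
                    n_df2=n_df2,
                    delta=math.nan,
                    sd_boot=math.nan,
                    z=math.nan,
                    p=math.nan,
                    alpha_adjusted=alpha_adj,
                    significant=False,
                    tested=False,
                )
            )
            continue
        rng = derive_rng(cfg.seed, "delta-bootstrap", bc.branch_id)
        delta, sd, z, p = bootstrap_delta_counts(
            (bc.n_concordant, bc.n_alt1, bc.n_alt2, bc.n_paraphyletic),
            cfg,
            rng,
        )
        results.append(
            DeltaResult(
                branch_id=bc.branch_id,
                n_concordant=bc.n_concordant,
                n_df1=n_df1,
                n_df2=n_df2,
                delta=delta,
                sd_boot=sd,
                z=z,
                p=p,
                alpha_adjusted=alpha_adj,
                significant=bool(p < alpha_adj),
                tested=True,
            )
        )
    return results


# ---------------------------------------------------------------------------
# Reporting
# ---------------------------------------------------------------------------

def results_to_dataframe(results: list[DeltaResult]):
    import pandas as pd

    return pd.DataFrame(
        [
            {
                "branch_id": r.branch_id,
                "n_concordant": r.n_concordant,
                "nDF1": r.n_df1,
                "nDF2": r.n_df2,
                "delta": r.delta,
                "sd_boot": r.sd_boot,
                "z": r.z,
                "p": r.p,
                "alpha_adjusted": r.alpha_adjusted,
                "significant": r.significant,
                "tested": r.tested,
            }
            for r in results
        ]
    )


def results_to_json(results: list[DeltaResult]) -> dict:
    def _num(x: float):
        return None if isinstance(x, float) and math.isnan(x) else x

    return {
        "n_branches": len(results),
        "n_tested": sum(r.tested for r in results),
        "n_significant": sum(r.significant for r in results),
        "branches": [
            {
                "branch_id": r.branch_id,
                "nDF1": r.n_df1,
                "nDF2": r.n_df2,
                "delta": _num(r.delta),
                "sd_boot": _num(r.sd_boot),
                "z": _num(r.z),
                "p": _num(r.p),
                "alpha_adjusted": _num(r.alpha_adjusted),
                "significant": r.significant,
                "tested": r.tested,
            }
            for r in results
        ],
    }
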
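"""Quantitation outside the array pipeline: EMSA isotherm K_D fitting and
2^-ddCt relative expression with significance testing.

The isotherm is the single-site hyperbola f = P / (K_D + P) (gel-shift
complexes here involve at most two dimers and the assays report a plain
K_D; a Hill coefficient is available behind a flag).  Relative expression
uses the classic 2^-ddCt estimator with per-biological-replicate pairing to
the reference gene and a Welch two-sample t-test on the dCt values.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats


@dataclass(frozen=True)
class KdFit:
    kd: float        # molar
    stderr: float    # molar, from the fit covariance
    hill: float | None = None


def _hyperbola(P, kd):
    return P / (kd + P)


def _hill(P, kd, n):
    return P**n / (kd**n + P**n)


def fit_kd(isotherm: pd.DataFrame, hill: bool = False) -> KdFit:
    """Least-squares fit of the binding isotherm.

    ``isotherm`` columns: protein_conc (molar, ascending, spanning at least
    one decade), fraction_bound.  Warns when the titration never reaches
    30% saturation (the K_D is then poorly constrained).
    """
    P = isotherm["protein_conc"].to_numpy(dtype=float)
    f = isotherm["fraction_bound"].to_numpy(dtype=float)
    if len(P) < 4:
        raise ValueError("need at least 4 titration points to fit a K_D")
    if P.max() / P.min() < 10:
        raise ValueError("titration must span at least one decade of concentration")
    if f.max() < 0.3:
        warnings.warn(
            "titration does not approach saturation (max fraction bound < 0.3); "
            "the fitted K_D will have a wide confidence interval",
            stacklevel=2,
        )
    # initial guess: concentration at half-saturation
    p0_kd = float(P[np.argmin(np.abs(f - 0.5))])
    if hill:
        popt, pcov = optimize.curve_fit(
            _hill, P, f, p0=[p0_kd, 1.0], bounds=([0, 0.1], [np.inf, 10]), maxfev=10000
        )
        return KdFit(kd=float(popt[0]), stderr=float(np.sqrt(pcov[0, 0])), hill=float(popt[1]))
    popt, pcov = optimize.curve_fit(
        _hyperbola, P, f, p0=[p0_kd], bounds=(0, np.inf), maxfev=10000
    )
    return KdFit(kd=float(popt[0]), stderr=float(np.sqrt(pcov[0, 0])))


@dataclass(frozen=True)
class DdctResult:
    fold: float      # mean 2^-ddCt, mutant vs WT
    sd: float        # across mutant bioreps
    p_value: float   # Welch t-test on per-biorep dCt values
    n_wt: int
    n_mutant: int


def ddct(cq: pd.DataFrame, ref_gene: str, target_gene: str) -> DdctResult:
    """Relative expression of ``target_gene`` (mutant vs WT) by 2^-ddCt.

    ``cq`` columns: gene_id, strain ('WT' | 'mutant'), biorep_id, cq.
    Per biorep, dCt = Cq_target - Cq_ref; ddCt per mutant biorep is taken
    against the mean WT dCt, folds are averaged across mutant bioreps, and
    a two-sided Welch t-test compares the two dCt groups.
    """
    dct: dict[str, np.ndarray] = {}
    for strain in ("WT", "mutant"):
        sub = cq[cq["strain"] == strain]
        ref = sub[sub["gene_id"] == ref_gene].set_index("biorep_id")["cq"]
        tgt = sub[sub["gene_id"] == target_gene].set_index("biorep_id")["cq"]
        missing = set(tgt.index) - set(ref.index)
        if missing or ref.empty:
            raise ValueError(
                f"reference gene {ref_gene!r} missing for strain {strain} "
                f"biorep(s) {sorted(missing) if missing else 'all'}"
            )
        if tgt.empty:
            raise ValueError(f"target gene {target_gene!r} absent for strain {strain}")
        dct[strain] = (tgt - ref.loc[tgt.index]).to_numpy(dtype=float)
    if min(len(dct["WT"]), len(dct["mutant"])) < 2:
        raise ValueError("need >= 2 biological replicates per strain")
    ddct_per_rep = dct["mutant"] - dct["WT"].mean()
    folds = 2.0 ** (-ddct_per_rep)
    t, p = stats.ttest_ind(dct["mutant"], dct["WT"], equal_var=False)
    if np.isnan(p):  # zero variance in both groups
        p = 1.0 if np.isclose(dct["mutant"].mean(), dct["WT"].mean()) else 0.0
    return DdctResult(
        fold=float(folds.mean()),
        sd=float(folds.std(ddof=1)) if len(folds) > 1 else 0.0,
        p_value=float(p),
        n_wt=len(dct["WT"]),
        n_mutant=len(dct["mutant"]),
    )
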
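"""Fit/prediction quality metrics and comparison reports.

Quality is quantified per quantity type by the Pearson correlation of
log-scale values and the geometric standard deviation of the residuals
(exponent of the root-mean-square log residual). Quantities backed by data
in a scenario are flagged "fitted", the rest "predicted". All states are
pooled. Enzymes of zero-flux reactions are absent from results and hence
excluded from the metrics.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd


def _check_pair(a: np.ndarray, b: np.ndarray, min_len: int) -> tuple[np.ndarray, np.ndarray]:
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("vectors must have equal length")
    if a.size < min_len:
        raise ValueError(f"need at least {min_len} points, got {a.size}")
    if np.any(a <= 0) or np.any(b <= 0):
        raise ValueError("all values must be positive")
    return a, b


def log_pearson(a: np.ndarray, b: np.ndarray) -> float:
    """Pearson correlation of (ln a, ln b); requires length >= 3."""
    a, b = _check_pair(a, b, 3)
    la, lb = np.log(a), np.log(b)
    if np.std(la) == 0 or np.std(lb) == 0:
        raise ValueError("correlation undefined for constant vector")
    return float(np.corrcoef(la, lb)[0, 1])


def geometric_sd_residuals(a: np.ndarray, b: np.ndarray) -> float:
    """exp(sqrt(mean((ln a - ln b)^2))); 1 means perfect agreement."""
    a, b = _check_pair(a, b, 1)
    return float(np.exp(np.sqrt(np.mean((np.log(a) - np.log(b)) ** 2))))


@dataclass
class ComparisonReport:
    """Per-quantity-type metrics plus the scatter table backing them."""

    metrics: pd.DataFrame  # columns: quantity, r_log, gsd, n, role
    scatter: pd.DataFrame  # columns: quantity, item, state, true, estimated, role


# which quantity types count as fitted per scenario name
_FITTED = {
    "S1": {"conc", "enzyme", "keq", "kcat", "km"},
    "S1K": {"conc", "enzyme", "keq"},
    "S2": {"conc", "enzyme"},
}


def build_report(truth, result, scenario) -> ComparisonReport:
    """Compare a truth bundle with a balancing result.

    ``truth`` is a :class:`~modelbalance.synthetic_data.TruthBundle`,
    ``result`` a :class:`~modelbalance.balancer.BalancingResult`, and
    ``scenario`` a :class:`~modelbalance.synthetic_data.Scenario` (or a
    scenario name string) controlling the fitted/predicted flags.
    """
    name = scenario if isinstance(scenario, str) else scenario.name
    if name not in _FITTED:
        raise ValueError(f"unknown scenario {name!r}")
    fitted = _FITTED[name]
    net = truth.network

    rows: list[dict] = []

    def _role(q):
        return "fitted" if q in fitted else "predicted"

    for sid, st in zip(truth.state_ids, truth.states):
        if sid not in result.x.columns:
            raise ValueError(f"state {sid!r} missing from result")
        for i, mid in enumerate(net.metabolite_ids):
            rows.append(
                dict(quantity="conc", item=mid, state=sid,
                     true=float(np.exp(st.x[i])),
                     estimated=float(np.exp(result.x.loc[mid, sid])),
                     role=_role("conc"))
            )
        z_est = result.z[sid]
        active = np.flatnonzero(st.v != 0)
        for l in active:
            rid = net.reaction_ids[l]
            if rid not in z_est.index:
                raise ValueError(f"active reaction {rid!r} missing from result")
            rows.append(
                dict(quantity="enzyme", item=rid, state=sid,
                     true=float(np.exp(st.z[l])),
                     estimated=float(np.exp(z_est[rid])),
                     role=_role("enzyme"))
            )

    tc, ec = truth.constants, result.constants
    for l, rid in enumerate(net.reaction_ids):
        rows.append(dict(quantity="keq", item=rid, state="",
                         true=float(np.exp(tc.ln_keq[l])),
                         estimated=float(np.exp(ec.ln_keq[l])),
                         role=_role("keq")))
        rows.append(dict(quantity="kcat", item=f"{rid}:fwd", state="",
                         true=float(np.exp(tc.ln_kcat_fwd[l])),
                         estimated=float(np.exp(ec.ln_kcat_fwd[l])),
                         role=_role("kcat")))
        rows.append(dict(quantity="kcat", item=f"{rid}:bwd", state="",
                         true=float(np.exp(tc.ln_kcat_bwd[l])),
                         estimated=float(np.exp(ec.ln_kcat_bwd[l])),
                         role=_role("kcat")))
    for k, (l, i) in enumerate(truth.schema.km_pairs):
        rows.append(dict(
            quantity="km",
            item=f"{net.reaction_ids[l]}:{net.metabolite_ids[i]}", state="",
            true=float(np.exp(tc.ln_km[k])),
            estimated=float(np.exp(ec.ln_km[k])),
            role=_role("km")))

    scatter = pd.DataFrame(rows)
    metrics_rows = []
    for quantity, grp in scatter.groupby("quantity", sort=False):
        t, e = grp["true"].to_numpy(), grp["estimated"].to_numpy()
        try:
            r = log_pearson(t, e)
        except ValueError:
            r = np.nan
        metrics_rows.append(
            dict(quantity=quantity, r_log=r, gsd=geometric_sd_residuals(t, e),
                 n=len(grp), role=grp["role"].iloc[0])
        )
    return ComparisonReport(metrics=pd.DataFrame(metrics_rows), scatter=scatter)
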
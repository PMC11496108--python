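"""Flux fitting and inference.

Weighted least-squares fit of a metabolic network model to MI-fraction and
uptake/release measurements, chi-square goodness of fit, per-measurement
residual influence, profile-likelihood confidence intervals, carbon-flow
decomposition, and the label-free FVA comparison.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize
from scipy.stats import chi2

from . import emu
from .emu import MixtureSpec, SimulationError, SubstrateLabeling
from .model_io import (
    FluxState,
    FreeFluxBasis,
    MetabolicNetwork,
    free_flux_basis,
)

__all__ = [
    "MeasurementRow",
    "MeasurementTable",
    "assemble_measurements",
    "FitProblem",
    "FitResult",
    "FluxCI",
    "CarbonFlowResult",
    "fit",
    "chi2_threshold",
    "residual_influence",
    "profile_ci",
    "carbon_flow",
    "label_free_fva",
]

MI_SD_FLOOR = 0.03


# ---------------------------------------------------------------------------
# measurements


@dataclass
class MeasurementRow:
    kind: str  # mi_fraction | exchange_flux | literature
    target: str | None  # metabolite/mixture id, or reaction id
    mean: float
    sd: float
    sd_floored: float
    mi: int | None = None
    coeffs: dict[str, float] | None = None  # literature: linear flux combination
    source: str = ""


@dataclass
class MeasurementTable:
    rows: list[MeasurementRow]

    @property
    def n(self) -> int:
        return len(self.rows)

    def by_kind(self, kind: str) -> list[MeasurementRow]:
        return [r for r in self.rows if r.kind == kind]

    def to_frame(self) -> pd.DataFrame:
        recs = []
        for r in self.rows:
            recs.append(
                {
                    "kind": r.kind,
                    "target": r.target,
                    "mi": r.mi,
                    "coeffs": ";".join(f"{k}:{v:g}" for k, v in (r.coeffs or {}).items())
                    or None,
                    "mean": r.mean,
                    "sd": r.sd,
                    "sd_floored": r.sd_floored,
                    "source": r.source,
                }
            )
        return pd.DataFrame(recs)

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "MeasurementTable":
        rows = []
        for _, rec in df.iterrows():
            coeffs = None
            if isinstance(rec.get("coeffs"), str) and rec["coeffs"]:
                coeffs = {
                    k: float(v)
                    for k, v in (p.split(":") for p in rec["coeffs"].split(";"))
                }
            mi = rec.get("mi")
            rows.append(
                MeasurementRow(
                    kind=rec["kind"],
                    target=rec["target"] if pd.notna(rec["target"]) else None,
                    mean=float(rec["mean"]),
                    sd=float(rec["sd"]),
                    sd_floored=float(rec["sd_floored"]),
                    mi=int(mi) if pd.notna(mi) else None,
                    coeffs=coeffs,
                    source=rec.get("source", "") or "",
                )
            )
        return cls(rows)


def assemble_measurements(
    mi_rows=(),
    exchange_rows=(),
    literature_rows=(),
    sd_floor: float = MI_SD_FLOOR,
    model: MetabolicNetwork | None = None,
    mixtures=(),
) -> MeasurementTable:
    """Build the fitting target table with sd flooring applied to MI rows.

    ``mi_rows``: iterable of (metabolite_or_mixture, mi_index, mean, sd), or a
    DataFrame from :func:`tracemfa.labeling.process_peak_areas` (rows with
    ``kept == False`` are dropped). ``exchange_rows``: (reaction, mean, sd).
    ``literature_rows``: (coeffs_dict, mean, sd, source). Raises ``KeyError``
    listing measurement ids absent from ``model`` (when given).
    """
    mixture_ids = {m.id for m in mixtures}
    rows: list[MeasurementRow] = []

    if isinstance(mi_rows, pd.DataFrame):
        df = mi_rows
        if "kept" in df.columns:
            df = df[df["kept"]]
        mi_rows = [
            (rec["metabolite"], int(rec["mi"]), float(rec["mean"]), float(rec["sd"]))
            for _, rec in df.iterrows()
            if pd.notna(rec["mean"])
        ]
    for met, mi, mean, sd in mi_rows:
        floored = max(float(sd), sd_floor) if np.isfinite(sd) else sd_floor
        rows.append(MeasurementRow("mi_fraction", met, float(mean), float(sd), floored, mi=mi))
    for rxn, mean, sd in exchange_rows:
        rows.append(
            MeasurementRow("exchange_flux", rxn, float(mean), float(sd), float(sd))
        )
    for coeffs, mean, sd, source in literature_rows:
        rows.append(
            MeasurementRow(
                "literature", None, float(mean), float(sd), float(sd),
                coeffs=dict(coeffs), source=source,
            )
        )

    if model is not None:
        known_mets = set(model.carbon_counts) | mixture_ids
        rxn_ids = set(model.reaction_ids)
        bad = sorted(
            {r.target for r in rows if r.kind == "mi_fraction" and r.target not in known_mets}
            | {r.target for r in rows if r.kind == "exchange_flux" and r.target not in rxn_ids}
            | {
                k
                for r in rows
                if r.kind == "literature"
                for k in r.coeffs
                if k not in rxn_ids
            }
        )
        if bad:
            raise KeyError(f"measurements reference unknown model ids: {bad}")
    return MeasurementTable(rows)


def chi2_threshold(n_measurements: int, p_parameters: int, quantile: float = 0.90) -> float:
    """Rejection threshold: ``quantile`` of chi-square with n - p dof."""
    dof = n_measurements - p_parameters
    if dof <= 0:
        raise ValueError(f"no degrees of freedom (n={n_measurements}, p={p_parameters})")
    return float(chi2.ppf(quantile, dof))


# ---------------------------------------------------------------------------
# fitting problem


def _stick_breaking(thetas: np.ndarray) -> np.ndarray:
    """Map k-1 parameters in [0,1] to a k-component convex weight vector."""
    w = np.empty(len(thetas) + 1)
    rest = 1.0
    for i, t in enumerate(thetas):
        w[i] = rest * t
        rest *= 1.0 - t
    w[-1] = rest
    return w


class FitProblem:
    """Everything needed to evaluate the weighted least-squares objective.

    Parameter vector layout: [free net fluxes | exchange fluxes of reversible
    reactions | stick-breaking mixture coordinates].
    """

    def __init__(
        self,
        network: MetabolicNetwork,
        labeling: SubstrateLabeling,
        table: MeasurementTable,
        mixtures: list[MixtureSpec] = (),
        basis: FreeFluxBasis | None = None,
        flux_bounds: dict | None = None,
        default_bound: float = 1000.0,
        exch_bound: float | None = None,
        penalty_weight: float = 1e4,
    ):
        self.network = network
        self.labeling = labeling
        self.table = table
        self.mixtures = {m.id: m for m in mixtures}
        self.basis = basis if basis is not None else free_flux_basis(network)
        self.penalty_weight = penalty_weight

        rxn_ids = network.reaction_ids
        self.reversible_ids = [r.id for r in network.reactions if r.reversible]
        self._irrev_rows = np.array(
            [self.basis.T[i] for i, r in enumerate(network.reactions) if not r.reversible]
        )

        # simulation targets: measured metabolites plus mixture components
        needed: set[str] = set()
        for row in table.by_kind("mi_fraction"):
            if row.target in self.mixtures:
                spec = self.mixtures[row.target]
                needed.update(c for c in spec.components if c not in spec.fixed_mids)
            else:
                needed.add(row.target)
        self.sim_targets = sorted(needed)
        self.graph = emu.emu_decompose(network, self.sim_targets) if needed else None

        nf = self.basis.n_free
        ne = len(self.reversible_ids)
        mixture_ids = sorted(self.mixtures)
        self.mixture_ids = mixture_ids
        nm = sum(len(self.mixtures[m].components) - 1 for m in mixture_ids)
        self.n_params = nf + ne + nm
        self._nf, self._ne, self._nm = nf, ne, nm

        lb = np.empty(self.n_params)
        ub = np.empty(self.n_params)
        flux_bounds = flux_bounds or {}
        irrev_free = {
            rid: not network.reaction(rid).reversible for rid in self.basis.free_ids
        }
        for k, rid in enumerate(self.basis.free_ids):
            lo = 0.0 if irrev_free[rid] else -default_bound
            hi = default_bound
            if rid in flux_bounds:
                lo, hi = flux_bounds[rid]
            lb[k], ub[k] = lo, hi
        eb = exch_bound if exch_bound is not None else default_bound
        lb[nf : nf + ne] = 0.0
        ub[nf : nf + ne] = eb
        lb[nf + ne :] = 0.0
        ub[nf + ne :] = 1.0
        self.bounds = (lb, ub)

        # linear residual machinery for flux-type rows
        self._ex_rows = table.by_kind("exchange_flux")
        self._lit_rows = table.by_kind("literature")
        self._mi_rows = table.by_kind("mi_fraction")
        T = self.basis.T
        idx = {r: i for i, r in enumerate(rxn_ids)}
        mats = []
        for row in self._ex_rows:
            mats.append(T[idx[row.target]])
        for row in self._lit_rows:
            combo = np.zeros(nf)
            for rid, c in row.coeffs.items():
                combo += c * T[idx[rid]]
            mats.append(combo)
        self._flux_design = np.array(mats) if mats else np.zeros((0, nf))
        self._flux_means = np.array([r.mean for r in self._ex_rows + self._lit_rows])
        self._flux_sds = np.array([r.sd_floored for r in self._ex_rows + self._lit_rows])
        self._mi_means = np.array([r.mean for r in self._mi_rows])
        self._mi_sds = np.array([r.sd_floored for r in self._mi_rows])

    # -- parameter vector helpers

    def split(self, theta: np.ndarray):
        nf, ne = self._nf, self._ne
        return theta[:nf], theta[nf : nf + ne], theta[nf + ne :]

    def mixture_weights(self, theta: np.ndarray) -> dict[str, np.ndarray]:
        _, _, mtheta = self.split(theta)
        out = {}
        pos = 0
        for mid in self.mixture_ids:
            k = len(self.mixtures[mid].components)
            out[mid] = _stick_breaking(mtheta[pos : pos + k - 1])
            pos += k - 1
        return out

    def flux_state(self, theta: np.ndarray) -> FluxState:
        free, exch, _ = self.split(theta)
        return self.basis.flux_state(
            free,
            exchange=dict(zip(self.reversible_ids, exch)),
            mixtures=self.mixture_weights(theta),
        )

    def net_flux_row(self, rxn_id: str) -> np.ndarray:
        """Net flux of a reaction as a linear function of theta."""
        row = np.zeros(self.n_params)
        row[: self._nf] = self.basis.net_row(rxn_id)
        return row

    def infeasibility(self, theta: np.ndarray) -> float:
        """Largest violation of irreversible-flux non-negativity."""
        if not len(self._irrev_rows):
            return 0.0
        free, _, _ = self.split(theta)
        v = self._irrev_rows @ free
        return float(max(0.0, -v.min()))

    # -- objective

    def simulated_measurement_mids(self, theta: np.ndarray) -> dict[str, np.ndarray]:
        flux = self.flux_state(theta)
        sim = (
            emu.simulate_mids(
                self.network, flux, self.labeling, self.sim_targets,
                graph=self.graph, warn_pruned=False,
            )
            if self.sim_targets
            else {}
        )
        weights = self.mixture_weights(theta)
        for mid_id, spec in self.mixtures.items():
            sim[mid_id] = emu.resolve_mixture_mid(spec, weights[mid_id], sim)
        return sim

    def residuals(self, theta: np.ndarray) -> np.ndarray:
        """Weighted measurement residuals (sim - meas) / sd, no penalties."""
        free, _, _ = self.split(theta)
        parts = []
        if self._mi_rows:
            try:
                sim = self.simulated_measurement_mids(theta)
                sim_vals = np.array(
                    [sim[r.target][r.mi] for r in self._mi_rows]
                )
                parts.append((sim_vals - self._mi_means) / self._mi_sds)
            except SimulationError:
                parts.append(np.full(len(self._mi_rows), 1e3))
        if len(self._flux_design):
            pred = self._flux_design @ free
            parts.append((pred - self._flux_means) / self._flux_sds)
        return np.concatenate(parts) if parts else np.zeros(0)

    def residuals_with_penalty(self, theta: np.ndarray) -> np.ndarray:
        res = self.residuals(theta)
        if len(self._irrev_rows):
            free, _, _ = self.split(theta)
            v = self._irrev_rows @ free
            pen = self.penalty_weight * np.clip(-v, 0.0, None)
            res = np.concatenate([res, pen])
        return res

    def ssr(self, theta: np.ndarray) -> float:
        r = self.residuals(theta)
        return float(r @ r)

    # -- starts

    def sample_start(self, rng: np.random.Generator, scale: float | None = None) -> np.ndarray:
        """Feasible-ish random start within bounds."""
        lb, ub = self.bounds
        if scale is None:
            scale = max(
                [abs(m) for m in self._flux_means if np.isfinite(m)] + [10.0]
            ) * 2.0
        lo = np.maximum(lb, -scale)
        hi = np.minimum(ub, scale)
        hi[self._nf : self._nf + self._ne] = np.minimum(
            ub[self._nf : self._nf + self._ne], scale / 2.0
        )
        best, best_viol = None, np.inf
        for _ in range(500):
            theta = rng.uniform(lo, hi)
            viol = self.infeasibility(theta)
            if viol <= 0:
                return theta
            if viol < best_viol:
                best, best_viol = theta, viol
        return best


@dataclass
class FitResult:
    theta: np.ndarray
    flux_state: FluxState
    ssr: float
    residuals: np.ndarray  # signed, per measurement row
    n: int
    p: int
    threshold: float
    accepted: bool
    start_index: int
    per_start_ssr: list[float]
    quantile: float = 0.90
    table: MeasurementTable | None = field(default=None, repr=False)

    @property
    def dof(self) -> int:
        return self.n - self.p


def fit(
    problem: FitProblem,
    n_starts: int = 10,
    seed: int = 0,
    quantile: float = 0.90,
    x0: np.ndarray | None = None,
    max_nfev: int | None = None,
    verbose: bool = False,
) -> FitResult:
    """Best-of-``n_starts`` local weighted least-squares fit.

    Deterministic for a fixed seed. Raises ``RuntimeError`` if every start
    fails to produce a finite, feasible solution.
    """
    rng = np.random.default_rng(seed)
    lb, ub = problem.bounds
    scale_hint = max(
        [abs(m) for m in problem._flux_means if np.isfinite(m)] + [10.0]
    )
    results = []
    diagnostics = []
    for s in range(n_starts):
        theta0 = (
            np.clip(x0, lb, ub)
            if (x0 is not None and s == 0)
            else problem.sample_start(rng)
        )
        try:
            sol = optimize.least_squares(
                problem.residuals_with_penalty,
                theta0,
                bounds=(lb, ub),
                method="trf",
                ftol=1e-12,
                xtol=1e-12,
                gtol=1e-12,
                max_nfev=max_nfev,
            )
            ssr = problem.ssr(sol.x)
            feasible = problem.infeasibility(sol.x) <= 1e-6 * max(1.0, scale_hint)
            if np.isfinite(ssr) and feasible:
                results.append((ssr, s, sol.x))
            diagnostics.append(f"start {s}: ssr={ssr:.6g} feasible={feasible}")
        except Exception as err:  # noqa: BLE001 - per-start diagnostics
            diagnostics.append(f"start {s}: failed ({err})")
        if verbose:
            print(diagnostics[-1])
    if not results:
        raise RuntimeError("all optimization starts failed:\n" + "\n".join(diagnostics))
    results.sort(key=lambda t: (t[0], t[1]))
    best_ssr, best_start, best_theta = results[0]
    n = problem.table.n
    p = problem.n_params
    # under-determined toy problems have no rejection region
    threshold = chi2_threshold(n, p, quantile) if n > p else float("inf")
    return FitResult(
        theta=best_theta,
        flux_state=problem.flux_state(best_theta),
        ssr=best_ssr,
        residuals=problem.residuals(best_theta),
        n=n,
        p=p,
        threshold=threshold,
        accepted=best_ssr <= threshold,
        start_index=best_start,
        per_start_ssr=[r[0] for r in sorted(results, key=lambda t: t[1])],
        quantile=quantile,
        table=problem.table,
    )


def residual_influence(fit_result: FitResult) -> pd.DataFrame:
    """Per-measurement squared residuals, largest first; sums to the SSR."""
    rows = fit_result.table.rows
    # residual order matches FitProblem.residuals: MI rows then flux rows
    ordered = (
        [r for r in rows if r.kind == "mi_fraction"]
        + [r for r in rows if r.kind == "exchange_flux"]
        + [r for r in rows if r.kind == "literature"]
    )
    recs = []
    for row, res in zip(ordered, fit_result.residuals):
        recs.append(
            {
                "kind": row.kind,
                "target": row.target if row.target else ";".join(row.coeffs or {}),
                "mi": row.mi,
                "mean": row.mean,
                "sd_floored": row.sd_floored,
                "residual": res,
                "residual_sq": res * res,
            }
        )
    df = pd.DataFrame(recs).sort_values("residual_sq", ascending=False)
    return df.reset_index(drop=True)


# ---------------------------------------------------------------------------
# profile-likelihood confidence intervals


@dataclass
class FluxCI:
    reaction: str
    estimate: float
    lower: float
    upper: float
    level: float = 0.90
    open_lower: bool = False
    open_upper: bool = False


def _box_extreme(problem: FitProblem, row: np.ndarray, sense: int) -> float:
    """Extreme of a linear flux functional under bounds + irreversibility only."""
    lb, ub = problem.bounds
    n = problem.n_params
    A_ub = None
    b_ub = None
    if len(problem._irrev_rows):
        G = np.zeros((len(problem._irrev_rows), n))
        G[:, : problem._nf] = -problem._irrev_rows
        A_ub, b_ub = G, np.zeros(len(G))
    res = optimize.linprog(
        sense * row, A_ub=A_ub, b_ub=b_ub, bounds=list(zip(lb, ub)), method="highs"
    )
    if not res.success:
        return sense * np.inf
    return float(sense * res.fun)


def profile_ci(
    problem: FitProblem,
    fit_result: FitResult,
    rxn_id: str,
    level: float = 0.90,
    delta: float | None = None,
    maxiter: int = 300,
) -> FluxCI:
    """Profile-likelihood CI: min/max net flux with SSR <= SSR_opt + delta.

    ``delta`` defaults to the chi-square(1 dof) quantile at ``level`` (2.706
    at 0.90). Endpoints that reach the extreme attainable under the bound
    constraints alone are flagged open-ended.
    """
    if delta is None:
        delta = float(chi2.ppf(level, 1))
    thr = fit_result.ssr + delta
    row = problem.net_flux_row(rxn_id)
    lb, ub = problem.bounds
    estimate = float(row @ fit_result.theta)
    scale = max(1.0, abs(estimate))

    cons = [
        {"type": "ineq", "fun": lambda th: thr - problem.ssr(th)},
    ]
    if len(problem._irrev_rows):
        G = np.zeros((len(problem._irrev_rows), problem.n_params))
        G[:, : problem._nf] = problem._irrev_rows
        cons.append({"type": "ineq", "fun": lambda th: G @ th, "jac": lambda th: G})

    ends = {}
    for sense, name in ((1.0, "lower"), (-1.0, "upper")):
        sol = optimize.minimize(
            lambda th: sense * float(row @ th),
            fit_result.theta,
            jac=lambda th: sense * row,
            bounds=list(zip(lb, ub)),
            constraints=cons,
            method="SLSQP",
            options={"maxiter": maxiter, "ftol": 1e-9},
        )
        val = float(row @ sol.x)
        ok = problem.ssr(sol.x) <= thr + 1e-3 * max(1.0, thr)
        if not ok:
            val = estimate  # conservative fallback: optimizer left the region
        ends[name] = val
    lower = min(ends["lower"], estimate)
    upper = max(ends["upper"], estimate)

    box_lo = _box_extreme(problem, row, 1)
    box_hi = _box_extreme(problem, row, -1)
    tol = 1e-4 * scale + 1e-6
    return FluxCI(
        reaction=rxn_id,
        estimate=estimate,
        lower=lower,
        upper=upper,
        level=level,
        open_lower=lower <= box_lo + tol,
        open_upper=upper >= box_hi - tol,
    )


# ---------------------------------------------------------------------------
# carbon flow


@dataclass
class CarbonFlowResult:
    flow: pd.DataFrame  # substrates x released products, carbon umol/g/day
    enrichments: pd.DataFrame  # e_ij
    release_rates: dict[str, float]  # product -> molecule release rate
    discounted: set[str]
    total_uptake_carbon: float

    @property
    def product_shares(self) -> pd.Series:
        tot = self.flow.to_numpy().sum()
        return self.flow.sum(axis=0) / tot if tot > 0 else self.flow.sum(axis=0)


def carbon_flow(
    network: MetabolicNetwork,
    flux: FluxState,
    discount_exchange: bool = True,
    flux_tol: float = 1e-9,
) -> CarbonFlowResult:
    """Carbon flow from each substrate to each released product.

    For each substrate i, MIDs are simulated with substrate i fully labeled
    and all others unlabeled; the flow to released product j is
    ``e_ij * r_j * n_carbons(j)``. Products of metabolites that are both
    taken up and released get ``e_ij = 0`` when ``discount_exchange`` is on.
    """
    substrates = sorted(network.substrates)

    # released products and their rates; remember the internal precursor
    release_rates: dict[str, float] = {}
    precursor: dict[str, str] = {}
    for r in network.reactions:
        if r.kind not in ("release", "sink"):
            continue
        v = flux.net_flux[r.id]
        if v <= flux_tol:
            continue
        carbon_products = [t for t in r.products if t.atoms is not None]
        for t in carbon_products:
            release_rates[t.met] = release_rates.get(t.met, 0.0) + v
            subs = [s for s in r.substrates if s.atoms is not None]
            if len(subs) == 1:
                precursor[t.met] = subs[0].met
    products = sorted(release_rates)

    taken_up = {
        t.met
        for r in network.reactions
        if r.kind == "uptake" and flux.net_flux[r.id] > flux_tol
        for t in r.products
    }
    discounted = (
        {p for p in products if precursor.get(p) in taken_up} if discount_exchange else set()
    )

    graph = emu.emu_decompose(network, products) if products else None
    counts = network.carbon_counts
    e = np.zeros((len(substrates), len(products)))
    for i, s in enumerate(substrates):
        lab = SubstrateLabeling(
            {m: np.full(counts.get(m, 1) or 1, 1.0 if m == s else 0.0) for m in substrates}
        )
        sim = emu.simulate_mids(network, flux, lab, products, graph=graph)
        for j, p in enumerate(products):
            if p in discounted:
                continue
            mid = sim[p]
            n = len(mid) - 1
            e[i, j] = float(np.dot(np.arange(n + 1), mid) / n)

    rate_vec = np.array([release_rates[p] * counts[p] for p in products])
    flow = pd.DataFrame(e * rate_vec, index=substrates, columns=products)
    enr = pd.DataFrame(e, index=substrates, columns=products)

    total_uptake = sum(
        flux.net_flux[r.id] * sum(t.n_carbons for t in r.substrates)
        for r in network.reactions
        if r.kind == "uptake" and flux.net_flux[r.id] > 0
    )
    return CarbonFlowResult(flow, enr, release_rates, discounted, float(total_uptake))


# ---------------------------------------------------------------------------
# label-free FVA


def label_free_fva(
    network: MetabolicNetwork,
    exchange_rows,
    literature_rows=(),
    z: float = 1.645,
    bound: float | None = None,
) -> pd.DataFrame:
    """Per-reaction (min, max) net flux from stoichiometry and exchange data only.

    Measured exchange fluxes constrain their reactions to mean +/- z*sd;
    literature rows constrain linear flux combinations likewise. Reversible
    reactions are unbounded (or +/- ``bound``); irreversible are >= 0.
    Returns a frame with columns reaction, min, max, bounded_low, bounded_high.
    Raises ``ValueError`` if the constraint set is infeasible.
    """
    from .model_io import stoichiometric_matrix

    S, _ = stoichiometric_matrix(network)
    rxn_ids = network.reaction_ids
    nr = len(rxn_ids)
    big = bound if bound is not None else None

    bounds = []
    for r in network.reactions:
        lo = 0.0 if not r.reversible else (-big if big is not None else None)
        hi = big
        bounds.append((lo, hi))
    idx = {r: i for i, r in enumerate(rxn_ids)}
    for rxn, mean, sd in exchange_rows:
        half = z * sd if np.isfinite(sd) else 0.0
        lo, hi = bounds[idx[rxn]]
        lo = mean - half if lo is None else max(lo, mean - half)
        hi = mean + half if hi is None else min(hi, mean + half)
        bounds[idx[rxn]] = (lo, hi)
    A_ub, b_ub = [], []
    for coeffs, mean, sd, _src in literature_rows:
        combo = np.zeros(nr)
        for rid, c in coeffs.items():
            combo[idx[rid]] = c
        half = z * sd if np.isfinite(sd) else 0.0
        A_ub.append(combo)
        b_ub.append(mean + half)
        A_ub.append(-combo)
        b_ub.append(-(mean - half))
    A_ub = np.array(A_ub) if A_ub else None
    b_ub = np.array(b_ub) if b_ub else None

    recs = []
    for j, rid in enumerate(rxn_ids):
        c = np.zeros(nr)
        c[j] = 1.0
        lohi = {}
        for sense, key in ((1.0, "min"), (-1.0, "max")):
            res = optimize.linprog(
                sense * c, A_ub=A_ub, b_ub=b_ub, A_eq=S, b_eq=np.zeros(S.shape[0]),
                bounds=bounds, method="highs",
            )
            if res.status == 3:  # unbounded
                lohi[key] = -np.inf if sense > 0 else np.inf
            elif res.status == 2:
                raise ValueError(
                    f"label-free FVA infeasible (first detected at {rid}); "
                    "check exchange constraints against stoichiometry"
                )
            elif not res.success:
                raise RuntimeError(f"linprog failed for {rid}: {res.message}")
            else:
                lohi[key] = float(sense * res.fun)
        recs.append(
            {
                "reaction": rid,
                "min": lohi["min"],
                "max": lohi["max"],
                "bounded_low": np.isfinite(lohi["min"]),
                "bounded_high": np.isfinite(lohi["max"]),
            }
        )
    return pd.DataFrame(recs)
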
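"""Synthetic ground-truth experiments for end-to-end testing.

Bundles small toy networks (for brute-force isotopomer cross-checks) and a
liver-like toy model with a futile glucose cycle, glycogenolysis, a condensed
TCA cycle, a urea-cycle fragment, amino-acid exchanges and protein turnover.
Generates noisy replicate measurement tables with a hidden truth record.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from . import emu, mfa
from .emu import MixtureSpec, SubstrateLabeling
from .model_io import (
    FluxState,
    FreeFluxBasis,
    MetabolicNetwork,
    free_flux_basis,
    parse_openflux,
)

__all__ = [
    "toy_networks",
    "liver_toy",
    "LiverToy",
    "SyntheticExperiment",
    "sample_flux_state",
    "generate_dataset",
    "recovery_report",
]

# --------------------------------------------------------------------------
# small oracle-checkable networks (<= 6 carbons, <= 10 reactions)

_TOY_SHEETS = {
    "chain": """\
rxnID,rxnEQ,rxnCTrans,rxnType
upt,S.ext = A,abc = abc,S
r1,A = B,abc = abc,FR
r2,B = C + D,abc = ab + c,F
rel1,C = C.out,ab = ab,E
rel2,D = D.out,a = a,E
""",
    "condense": """\
rxnID,rxnEQ,rxnCTrans,rxnType
u1,X.ext = X,ab = ab,S
u2,Y.ext = Y,c = c,S
c1,X + Y = Z,ab + c = abc,F
s1,Z = W + V,abc = bc + a,F
e1,W = W.out,ab = ab,E
e2,V = V.out,a = a,E
""",
    "cycle": """\
rxnID,rxnEQ,rxnCTrans,rxnType
u1,AC.ext = AC,ab = ab,S
u2,OX.ext = OX,cdef = cdef,S
c1,AC + OX = CIT,ab + cdef = abcdef,F
c2,CIT = AKG + CO2,abcdef = abcde + f,F
c3,AKG = OX + CO2,abcde = bcde + a,F
g1,AKG = GLU,abcde = abcde,FR
e1,CO2 = CO2.out,a = a,E
e2,GLU = GLU.out,abcde = abcde,E
""",
    "split": """\
rxnID,rxnEQ,rxnCTrans,rxnType
u,S.ext = S6,abcdef = abcdef,S
sp,S6 = T1 + T2,abcdef = cba + def,F
iso,T1 = T2,abc = abc,FR
cond,T2 + T2 = H,abc + def = abcdef,F
rel,H = H.out,abcdef = abcdef,E
relT,T1 = T1.out,abc = abc,E
""",
}

_TOY_LABELING = {
    "chain": {"S.ext": (3, 0.8)},
    "condense": {"X.ext": (2, 1.0), "Y.ext": (1, 0.5)},
    "cycle": {"AC.ext": (2, 1.0), "OX.ext": (4, 0.0)},
    "split": {"S.ext": (6, 0.9)},
}


def toy_networks() -> dict[str, tuple[MetabolicNetwork, SubstrateLabeling]]:
    """Bundled small networks with a default substrate labeling each."""
    out = {}
    for name, sheet in _TOY_SHEETS.items():
        net = parse_openflux(sheet)
        out[name] = (net, SubstrateLabeling.uniform(_TOY_LABELING[name]))
    return out


# --------------------------------------------------------------------------
# liver-like toy model

LIVER_TOY_SHEET = """\
rxnID,rxnEQ,rxnCTrans,rxnType
glc_upt,GLC.ext = GLC,abcdef = abcdef,S
glc_rel,GLC = GLC.rel,abcdef = abcdef,E
gk,GLC = G6P,abcdef = abcdef,F
g6pase,G6P = GLC,abcdef = abcdef,F
glycogen,GLYC.ext = G6P,abcdef = abcdef,S
glycolysis,G6P = TRI + TRI,abcdef = cba + def,F
gng,TRI + TRI = G6P,abc + def = cbadef,F
triopyr,TRI = PYR,abc = abc,FR
ldh,PYR = LAC,abc = abc,FR
lac_rel,LAC = LAC.rel,abc = abc,E
ala_upt,ALA.ext = ALA,abc = abc,S
alat,ALA = PYR,abc = abc,F
pdh,PYR = ACA + CO2,abc = bc + a,F
pc,PYR + CO2 = OAA,abc + d = abcd,F
cs,ACA + OAA = AKG + CO2,ab + cdef = abcde + f,F
akgdh,AKG = OAA + CO2,abcde = bcde + a,F
gdh,GLU = AKG,abcde = abcde,FR
glu_rel,GLU = GLU.rel,abcde = abcde,E
arg_upt,ARG.ext = ARG,abcdef = abcdef,S
arginase,ARG = GLU + UREA,abcdef = abcde + f,F
urea_rel,UREA = UREA.rel,a = a,E
protsyn,ALA + GLU = PROT.snk,abc + defgh = abcdefgh,B
protdeg,PROT.ext = ALA + GLU,abcdefgh = abc + defgh,S
pepck,OAA = TRI + CO2,abcd = abc + d,F
co2_rel,CO2 = CO2.rel,a = a,E
"""

TRUE_NET_FLUX = {
    "glc_upt": 20.0, "glc_rel": 10.0, "gk": 40.0, "g6pase": 30.0,
    "glycogen": 50.0, "glycolysis": 65.0, "gng": 5.0, "triopyr": 130.0,
    "ldh": 58.0, "lac_rel": 58.0, "ala_upt": 30.0, "alat": 25.0,
    "pdh": 70.0, "pc": 27.0, "cs": 70.0, "akgdh": 53.0, "gdh": -17.0,
    "glu_rel": 22.0, "arg_upt": 10.0, "arginase": 10.0, "urea_rel": 10.0,
    "protsyn": 25.0, "protdeg": 20.0, "pepck": 10.0, "co2_rel": 176.0,
}
TRUE_EXCHANGE_FLUX = {"triopyr": 20.0, "ldh": 15.0, "gdh": 5.0}
TRUE_MEDIUM_ALPHA = 0.4  # fresh-medium share in spent-medium glucose

# deep-labeling design: medium glucose and amino acids fully 13C; tissue
# glycogen and pre-existing protein unlabeled (12C dilution source)
DEEP_LABELING = {
    "GLC.ext": (6, 1.0),
    "ALA.ext": (3, 1.0),
    "ARG.ext": (6, 1.0),
    "GLYC.ext": (6, 0.0),
    "PROT.ext": (8, 0.0),
}

MEASURED_METS = ["GLC", "LAC", "GLU", "ALA", "GLC.medium"]

# measured uptake/release reaction fluxes (reaction-space means, sd)
EXCHANGE_MEASUREMENTS = [
    ("ala_upt", 3.0), ("arg_upt", 1.0), ("lac_rel", 5.0),
    ("glu_rel", 2.0), ("urea_rel", 1.0),
]
LITERATURE_CONSTRAINTS = [
    ({"glc_rel": 1.0, "glc_upt": -1.0}, 2.0, "net glucose release (medium assay)"),
    ({"protdeg": 1.0}, 2.0, "protein degradation (literature)"),
    ({"protsyn": 1.0}, 2.5, "protein synthesis (literature)"),
]

# fluxes with informative profile CIs on this design (checked empirically;
# excludes pure pass-through and exchange-degenerate reactions)
IDENTIFIABLE_FLUXES = ["glycogen", "gk", "g6pase", "pdh", "cs", "ala_upt", "protsyn"]


@dataclass
class LiverToy:
    network: MetabolicNetwork
    labeling: SubstrateLabeling
    basis: FreeFluxBasis
    true_flux: FluxState
    mixtures: list[MixtureSpec]
    measured_mets: list[str]
    identifiable: list[str]

    def fit_problem(self, table: mfa.MeasurementTable, **kwargs) -> mfa.FitProblem:
        kwargs.setdefault("default_bound", 500.0)
        kwargs.setdefault("exch_bound", 100.0)
        return mfa.FitProblem(
            self.network, self.labeling, table, mixtures=self.mixtures,
            basis=self.basis, **kwargs,
        )


def liver_toy() -> LiverToy:
    net = parse_openflux(LIVER_TOY_SHEET)
    labeling = SubstrateLabeling.uniform(DEEP_LABELING)
    basis = free_flux_basis(net)
    true_flux = FluxState(
        dict(TRUE_NET_FLUX),
        dict(TRUE_EXCHANGE_FLUX),
        {"GLC.medium": np.array([TRUE_MEDIUM_ALPHA, 1.0 - TRUE_MEDIUM_ALPHA])},
    )
    fresh_glc = labeling.mid("GLC.ext")  # fully labeled fresh-medium glucose
    mixtures = [
        MixtureSpec("GLC.medium", ["fresh", "GLC"], {"fresh": fresh_glc})
    ]
    return LiverToy(
        net, labeling, basis, true_flux, mixtures, list(MEASURED_METS),
        list(IDENTIFIABLE_FLUXES),
    )


# --------------------------------------------------------------------------
# experiment generation


@dataclass
class SyntheticExperiment:
    toy: LiverToy
    replicates: int = 3
    noise_sd: float = 0.03
    seed: int = 0
    sd_floor: float = mfa.MI_SD_FLOOR
    exchange_specs: list = field(default_factory=lambda: list(EXCHANGE_MEASUREMENTS))
    literature_specs: list = field(default_factory=lambda: list(LITERATURE_CONSTRAINTS))


def sample_flux_state(
    network: MetabolicNetwork,
    basis: FreeFluxBasis,
    bounds: dict[str, tuple[float, float]],
    seed: int = 0,
    exchange_bounds: tuple[float, float] = (0.0, 50.0),
    max_attempts: int = 10000,
) -> FluxState:
    """Rejection-sample a steady-state flux vector with valid signs.

    ``bounds`` maps each free reaction id to its sampling interval.
    """
    rng = np.random.default_rng(seed)
    irrev = {r.id for r in network.reactions if not r.reversible}
    rxn_ids = network.reaction_ids
    lo = np.array([bounds[r][0] for r in basis.free_ids])
    hi = np.array([bounds[r][1] for r in basis.free_ids])
    for _ in range(max_attempts):
        v_free = rng.uniform(lo, hi)
        v = basis.full_vector(v_free)
        if all(v[i] >= 0 for i, r in enumerate(rxn_ids) if r in irrev):
            exch = {
                r.id: float(rng.uniform(*exchange_bounds))
                for r in network.reactions
                if r.reversible
            }
            return basis.flux_state(v_free, exchange=exch)
    raise RuntimeError(
        f"no feasible flux vector found in {max_attempts} draws; widen the bounds"
    )


def _noisy_mid(mid: np.ndarray, sd: float, rng: np.random.Generator) -> np.ndarray:
    noisy = mid + rng.normal(0.0, sd, size=len(mid)) if sd > 0 else mid.copy()
    noisy = np.clip(noisy, 0.0, None)
    total = noisy.sum()
    if total <= 0:
        noisy = mid.copy()
        total = noisy.sum()
    return noisy / total

def generate_dataset(exp: SyntheticExperiment):
    """Simulate the truth, add replicate noise, emit (table, truth record).

    MID noise is additive Gaussian with clip-and-renormalize per replicate;
    flux measurements get Gaussian noise at their stated sd. With
    ``noise_sd = 0`` the table means equal the simulated values exactly.
    """
    toy = exp.toy
    rng = np.random.default_rng(exp.seed)
    flux = toy.true_flux
    sim_targets = [m for m in toy.measured_mets if m in toy.network.carbon_counts]
    sim = emu.simulate_mids(toy.network, flux, toy.labeling, sim_targets)
    for spec in toy.mixtures:
        if spec.id in toy.measured_mets:
            sim[spec.id] = emu.resolve_mixture_mid(
                spec, flux.mixture_coefficients[spec.id], sim
            )

    mi_rows = []
    true_mids = {}
    for met in toy.measured_mets:
        mid = sim[met]
        true_mids[met] = mid.tolist()
        reps = np.array(
            [_noisy_mid(mid, exp.noise_sd, rng) for _ in range(exp.replicates)]
        )
        mean = reps.mean(axis=0)
        sd = reps.std(axis=0, ddof=1) if exp.replicates > 1 else np.zeros(len(mid))
        if exp.noise_sd == 0:
            mean, sd = mid, np.zeros(len(mid))
        for i in range(len(mid)):
            mi_rows.append((met, i, float(mean[i]), float(sd[i])))

    exchange_rows = []
    for rxn, sd in exp.exchange_specs:
        true_v = flux.net_flux[rxn]
        mean = true_v + (rng.normal(0.0, sd) if exp.noise_sd > 0 else 0.0)
        exchange_rows.append((rxn, float(mean), float(sd)))
    literature_rows = []
    for coeffs, sd, source in exp.literature_specs:
        true_v = sum(c * flux.net_flux[r] for r, c in coeffs.items())
        mean = true_v + (rng.normal(0.0, sd) if exp.noise_sd > 0 else 0.0)
        literature_rows.append((coeffs, float(mean), float(sd), source))

    table = mfa.assemble_measurements(
        mi_rows, exchange_rows, literature_rows,
        sd_floor=exp.sd_floor, model=toy.network, mixtures=toy.mixtures,
    )
    truth = {
        "net_flux": dict(flux.net_flux),
        "exchange_flux": dict(flux.exchange_flux),
        "mixture_coefficients": {
            k: np.asarray(v).tolist() for k, v in flux.mixture_coefficients.items()
        },
        "true_mids": true_mids,
        "seed": exp.seed,
        "noise_sd": exp.noise_sd,
        "replicates": exp.replicates,
    }
    return table, truth


def recovery_report(truth: dict, fit_result: mfa.FitResult, cis: list[mfa.FluxCI]) -> dict:
    """Per-flux errors and CI coverage against the hidden truth."""
    fluxes = {}
    for rxn, true_v in truth["net_flux"].items():
        est = fit_result.flux_state.net_flux[rxn]
        fluxes[rxn] = {
            "true": true_v,
            "estimate": est,
            "abs_error": abs(est - true_v),
            "rel_error": abs(est - true_v) / max(abs(true_v), 1e-12),
        }
    covered = []
    for ci in cis:
        true_v = truth["net_flux"][ci.reaction]
        hit = ci.lower - 1e-9 <= true_v <= ci.upper + 1e-9
        fluxes[ci.reaction]["ci"] = [ci.lower, ci.upper]
        fluxes[ci.reaction]["covered"] = hit
        covered.append(hit)
    return {
        "fluxes": fluxes,
        "ssr": fit_result.ssr,
        "chi2_threshold": fit_result.threshold,
        "chi2_accepted": fit_result.accepted,
        "coverage_rate": float(np.mean(covered)) if covered else None,
        "n_cis": len(covered),
    }


def write_bundle(exp: SyntheticExperiment, out_dir) -> None:
    """Emit model sheet, labeling config, measurement TSV and truth JSON."""
    import pathlib

    import yaml

    from .model_io import serialize_openflux

    out = pathlib.Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    table, truth = generate_dataset(exp)
    (out / "model.csv").write_text(serialize_openflux(exp.toy.network))
    labeling_cfg = {
        m: {"n": len(p), "enrichment": float(p[0])}
        for m, p in exp.toy.labeling.positional.items()
    }
    (out / "labeling.yaml").write_text(yaml.safe_dump(labeling_cfg, sort_keys=True))
    table.to_frame().to_csv(out / "measurements.tsv", sep="\t", index=False)
    (out / "truth.json").write_text(json.dumps(truth, indent=2, sort_keys=True))
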
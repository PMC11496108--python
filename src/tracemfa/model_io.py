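"""Atom-mapped metabolic network models in the OpenFLUX sheet dialect.

A model sheet is a delimited table (comma or tab) with columns

    rxnID, rxnEQ, rxnCTrans, rxnType

one row per reaction. ``rxnEQ`` is a chemical equation like ``A + B = C``;
``rxnCTrans`` gives one carbon-transition string per equation term, using
lower-case letters as per-reaction local atom identifiers (``ab + c = abc``).
Terms that carry no mapped carbon (cofactors, O2, ATP...) use ``X`` (or ``-``)
as their transition. Recognized reaction types:

    F   irreversible internal reaction (default when the column is absent)
    FR  reversible internal reaction
    S   uptake: left-hand metabolites are external substrates
    E   release: right-hand metabolites are external sinks
    B   biomass/sink: right-hand side leaves the balanced set; carbon balance
        is not enforced

Carbon-carrying terms must have unit stoichiometry; write ``A + A`` rather
than ``2 A``. Non-carbon terms may carry fractional coefficients.
"""

from __future__ import annotations

import io
import json
import re
from dataclasses import dataclass, field

import numpy as np
from scipy.linalg import qr

__all__ = [
    "Term",
    "Reaction",
    "MetabolicNetwork",
    "FluxState",
    "FreeFluxBasis",
    "ModelValidationError",
    "ModelParseError",
    "parse_openflux",
    "serialize_openflux",
    "stoichiometric_matrix",
    "free_flux_basis",
    "network_summary",
]

_TYPE_MAP = {
    "F": ("internal", False),
    "FR": ("internal", True),
    "S": ("uptake", False),
    "E": ("release", False),
    "B": ("sink", False),
}
_NO_CARBON = {"", "X", "x", "-"}


class ModelParseError(ValueError):
    """Raised when a model sheet cannot be parsed."""


class ModelValidationError(ValueError):
    """Raised when a parsed model violates a structural invariant."""


@dataclass(frozen=True)
class Term:
    """One molecule instance in a reaction equation."""

    met: str
    coeff: float = 1.0
    atoms: str | None = None  # transition letters, None for carbon-free terms

    @property
    def n_carbons(self) -> int:
        return 0 if self.atoms is None else len(self.atoms)


@dataclass(frozen=True)
class Reaction:
    id: str
    substrates: tuple[Term, ...]
    products: tuple[Term, ...]
    reversible: bool = False
    kind: str = "internal"  # internal | uptake | release | sink

    def stoich(self) -> dict[str, float]:
        """Net stoichiometric coefficients (products minus substrates)."""
        out: dict[str, float] = {}
        for t in self.substrates:
            out[t.met] = out.get(t.met, 0.0) - t.coeff
        for t in self.products:
            out[t.met] = out.get(t.met, 0.0) + t.coeff
        return out


@dataclass
class MetabolicNetwork:
    reactions: list[Reaction]
    balanced_metabolites: set[str] = field(default_factory=set)
    substrates: set[str] = field(default_factory=set)
    sinks: set[str] = field(default_factory=set)
    carbon_counts: dict[str, int] = field(default_factory=dict)
    compartment_pools: dict[str, list[str]] = field(default_factory=dict)

    def reaction(self, rxn_id: str) -> Reaction:
        for r in self.reactions:
            if r.id == rxn_id:
                return r
        raise KeyError(rxn_id)

    @property
    def reaction_ids(self) -> list[str]:
        return [r.id for r in self.reactions]

    def n_carbons(self, met: str) -> int:
        return self.carbon_counts.get(met, 0)


@dataclass
class FluxState:
    """Point in flux space: net fluxes, exchange fluxes, mixture weights.

    Net fluxes are in umol per gram tissue per day; exchange fluxes are the
    non-negative bidirectional component of reversible reactions; mixture
    coefficients are convex weight vectors keyed by mixture id.
    """

    net_flux: dict[str, float]
    exchange_flux: dict[str, float] = field(default_factory=dict)
    mixture_coefficients: dict[str, np.ndarray] = field(default_factory=dict)

    def net_vector(self, order: list[str]) -> np.ndarray:
        return np.array([self.net_flux[r] for r in order], dtype=float)


# ---------------------------------------------------------------------------
# parsing


def _parse_side(text: str) -> list[tuple[str, float]]:
    terms = []
    for chunk in text.split("+"):
        chunk = chunk.strip()
        if not chunk:
            raise ModelParseError(f"empty term in equation side {text!r}")
        m = re.match(r"^(\d+(?:\.\d+)?)\s+(\S.*)$", chunk)
        if m:
            terms.append((m.group(2).strip(), float(m.group(1))))
        else:
            terms.append((chunk, 1.0))
    return terms


def _parse_trans_side(text: str) -> list[str | None]:
    out: list[str | None] = []
    for chunk in text.split("+"):
        chunk = chunk.strip()
        out.append(None if chunk in _NO_CARBON else chunk)
    return out


def _split_eq(text: str, what: str, rxn_id: str) -> tuple[str, str]:
    parts = text.split("=")
    if len(parts) != 2:
        raise ModelParseError(f"reaction {rxn_id}: {what} must contain exactly one '='")
    return parts[0], parts[1]


def _build_reaction(rxn_id: str, eq: str, trans: str, rtype: str) -> Reaction:
    rtype = (rtype or "F").strip().upper()
    if rtype not in _TYPE_MAP:
        raise ModelParseError(f"reaction {rxn_id}: unknown reaction type {rtype!r}")
    kind, reversible = _TYPE_MAP[rtype]

    lhs, rhs = _split_eq(eq, "equation", rxn_id)
    subs = _parse_side(lhs)
    prods = _parse_side(rhs)

    if trans.strip():
        tl, tr = _split_eq(trans, "carbon transitions", rxn_id)
        sub_atoms = _parse_trans_side(tl)
        prod_atoms = _parse_trans_side(tr)
    else:
        sub_atoms = [None] * len(subs)
        prod_atoms = [None] * len(prods)
    if len(sub_atoms) != len(subs) or len(prod_atoms) != len(prods):
        raise ModelParseError(
            f"reaction {rxn_id}: carbon-transition terms do not align with equation terms"
        )

    def mk(pairs, atoms):
        out = []
        for (met, coeff), a in zip(pairs, atoms):
            if a is not None and coeff != 1.0:
                raise ModelParseError(
                    f"reaction {rxn_id}: carbon-carrying term {met!r} must have "
                    f"unit stoichiometry (write the term twice instead of '2 {met}')"
                )
            out.append(Term(met, coeff, a))
        return tuple(out)

    return Reaction(rxn_id, mk(subs, sub_atoms), mk(prods, prod_atoms), reversible, kind)


def _validate(net: MetabolicNetwork) -> None:
    # carbon-letter balance, letter uniqueness, per-metabolite carbon counts
    counts: dict[str, int] = {}
    for r in net.reactions:
        sub_letters: list[str] = []
        prod_letters: list[str] = []
        for side, bag in ((r.substrates, sub_letters), (r.products, prod_letters)):
            for t in side:
                if t.atoms is not None:
                    bag.extend(t.atoms)
        for bag, side in ((sub_letters, "substrate"), (prod_letters, "product")):
            if len(bag) != len(set(bag)):
                raise ModelValidationError(
                    f"reaction {r.id}: repeated carbon letter on {side} side"
                )
        if r.kind != "sink" and sorted(sub_letters) != sorted(prod_letters):
            raise ModelValidationError(
                f"reaction {r.id}: carbon letters unbalanced "
                f"({''.join(sorted(sub_letters))} vs {''.join(sorted(prod_letters))})"
            )
        if r.kind == "sink" and not set(prod_letters) <= set(sub_letters):
            raise ModelValidationError(
                f"reaction {r.id}: sink products introduce new carbon letters"
            )
        for t in (*r.substrates, *r.products):
            if t.atoms is None:
                continue
            prev = counts.setdefault(t.met, t.n_carbons)
            if prev != t.n_carbons:
                raise ModelValidationError(
                    f"metabolite {t.met}: inconsistent carbon count "
                    f"({prev} vs {t.n_carbons} in reaction {r.id})"
                )
    net.carbon_counts = counts


def _classify_metabolites(net: MetabolicNetwork) -> None:
    all_mets = {t.met for r in net.reactions for t in (*r.substrates, *r.products)}
    substrates = {t.met for r in net.reactions if r.kind == "uptake" for t in r.substrates}
    sinks = {
        t.met
        for r in net.reactions
        if r.kind in ("release", "sink")
        for t in r.products
    }
    net.substrates = substrates
    net.sinks = sinks - substrates
    net.balanced_metabolites = all_mets - substrates - net.sinks


def parse_openflux(text_or_path, compartment_pools=None) -> MetabolicNetwork:
    """Parse an OpenFLUX-dialect model sheet into a validated network.

    Parameters
    ----------
    text_or_path
        Sheet content as a string, a file-like object, or a filesystem path.
    compartment_pools
        Optional mapping metabolite -> list of pool species ids, attached to
        the returned network for use by mixture modelling.
    """
    if hasattr(text_or_path, "read"):
        text = text_or_path.read()
    else:
        s = str(text_or_path)
        if "\n" not in s and ("," not in s):
            with open(s) as fh:
                text = fh.read()
        else:
            text = s

    lines = [ln for ln in text.splitlines() if ln.strip() and not ln.lstrip().startswith("#")]
    if not lines:
        raise ModelParseError("empty model sheet")
    delim = "\t" if "\t" in lines[0] else ","

    rows = list(_sheet_rows(lines, delim))
    reactions = []
    seen = set()
    for rxn_id, eq, trans, rtype in rows:
        if rxn_id in seen:
            raise ModelParseError(f"duplicate reaction id {rxn_id!r}")
        seen.add(rxn_id)
        reactions.append(_build_reaction(rxn_id, eq, trans, rtype))

    net = MetabolicNetwork(reactions, compartment_pools=dict(compartment_pools or {}))
    _validate(net)
    _classify_metabolites(net)
    return net


def _sheet_rows(lines, delim):
    header = [c.strip() for c in lines[0].split(delim)]
    lower = [h.lower() for h in header]
    if "rxnid" in lower:
        idx = {
            "id": lower.index("rxnid"),
            "eq": lower.index("rxneq"),
            "trans": lower.index("rxnctrans"),
            "type": lower.index("rxntype") if "rxntype" in lower else None,
        }
        body = lines[1:]
    else:  # headerless sheet: positional columns
        idx = {"id": 0, "eq": 1, "trans": 2, "type": 3}
        body = lines

    for ln in body:
        cells = [c.strip() for c in ln.split(delim)]
        if len(cells) < 3:
            raise ModelParseError(f"row has fewer than 3 columns: {ln!r}")
        rtype = ""
        if idx["type"] is not None and idx["type"] < len(cells):
            rtype = cells[idx["type"]]
        yield cells[idx["id"]], cells[idx["eq"]], cells[idx["trans"]], rtype


_TYPE_CODE = {("internal", False): "F", ("internal", True): "FR",
              ("uptake", False): "S", ("release", False): "E", ("sink", False): "B"}


def serialize_openflux(net: MetabolicNetwork, delim: str = ",") -> str:
    """Emit the network back as a model sheet in the same dialect."""

    def fmt_side(terms, atoms=False):
        parts = []
        for t in terms:
            if atoms:
                parts.append(t.atoms if t.atoms is not None else "X")
            else:
                parts.append(t.met if t.coeff == 1.0 else f"{t.coeff:g} {t.met}")
        return " + ".join(parts)

    out = io.StringIO()
    out.write(delim.join(["rxnID", "rxnEQ", "rxnCTrans", "rxnType"]) + "\n")
    for r in net.reactions:
        eq = f"{fmt_side(r.substrates)} = {fmt_side(r.products)}"
        tr = f"{fmt_side(r.substrates, True)} = {fmt_side(r.products, True)}"
        out.write(delim.join([r.id, eq, tr, _TYPE_CODE[(r.kind, r.reversible)]]) + "\n")
    return out.getvalue()


# ---------------------------------------------------------------------------
# stoichiometry and the free-flux parameterization


def stoichiometric_matrix(net: MetabolicNetwork):
    """Signed stoichiometric matrix over balanced metabolites x reactions.

    Returns ``(S, met_order)`` with reaction columns in network order.
    """
    mets = sorted(net.balanced_metabolites)
    row = {m: i for i, m in enumerate(mets)}
    S = np.zeros((len(mets), len(net.reactions)))
    for j, r in enumerate(net.reactions):
        for met, coeff in r.stoich().items():
            if met in row:
                S[row[met], j] += coeff
    return S, mets


class FreeFluxBasis:
    """Parameterization of the steady-state flux space by free fluxes.

    The stoichiometric constraint ``S v = 0`` is solved by selecting a set of
    free reactions and expressing all remaining (dependent) net fluxes as a
    linear map ``v = T v_free``.
    """

    def __init__(self, net: MetabolicNetwork, free_ids: list[str], T: np.ndarray):
        self.network = net
        self.free_ids = list(free_ids)
        self.T = T  # (n_reactions, n_free), rows in network reaction order

    @property
    def n_free(self) -> int:
        return len(self.free_ids)

    def full_vector(self, v_free: np.ndarray) -> np.ndarray:
        return self.T @ np.asarray(v_free, dtype=float)

    def flux_state(self, v_free, exchange=None, mixtures=None) -> FluxState:
        v = self.full_vector(v_free)
        net_flux = dict(zip(self.network.reaction_ids, v))
        return FluxState(net_flux, dict(exchange or {}), dict(mixtures or {}))

    def net_row(self, rxn_id: str) -> np.ndarray:
        """Row of T giving a reaction's net flux as a function of v_free."""
        return self.T[self.network.reaction_ids.index(rxn_id)]


def free_flux_basis(net: MetabolicNetwork, fixed=()) -> FreeFluxBasis:
    """Build a free-flux parameterization, forcing ``fixed`` reactions free.

    Raises :class:`ModelValidationError` if the requested fixed reactions are
    linearly dependent given the stoichiometry (they could not be assigned
    independently).
    """
    S, _ = stoichiometric_matrix(net)
    rxn_ids = net.reaction_ids
    n = len(rxn_ids)
    fixed = list(fixed)
    unknown = [f for f in fixed if f not in rxn_ids]
    if unknown:
        raise KeyError(f"fixed reactions not in network: {unknown}")

    rank = np.linalg.matrix_rank(S) if S.size else 0
    forced_idx = [rxn_ids.index(f) for f in fixed]
    rest_idx = [j for j in range(n) if j not in set(forced_idx)]

    S_rest = S[:, rest_idx] if rest_idx else np.zeros((S.shape[0], 0))
    rank_rest = np.linalg.matrix_rank(S_rest) if S_rest.size else 0
    if rank_rest < rank:
        raise ModelValidationError(
            f"requested free reactions {fixed} are dependent: removing them "
            f"drops the stoichiometric rank from {rank} to {rank_rest}"
        )

    # pivot (dependent) columns chosen among the remaining reactions
    if S_rest.size and rank:
        _, _, piv = qr(S_rest, pivoting=True)
        dep_local = sorted(piv[:rank])
    else:
        dep_local = []
    dep_idx = [rest_idx[j] for j in dep_local]
    free_idx = forced_idx + [j for j in rest_idx if j not in set(dep_idx)]
    free_idx = sorted(free_idx)

    T = np.zeros((n, len(free_idx)))
    for k, j in enumerate(free_idx):
        T[j, k] = 1.0
    if dep_idx:
        S_dep = S[:, dep_idx]
        S_free = S[:, free_idx]
        # exact because span(S_free) subset span(S_dep) by construction
        coeffs, *_ = np.linalg.lstsq(S_dep, -S_free, rcond=None)
        resid = S_dep @ coeffs + S_free
        if np.max(np.abs(resid)) > 1e-8:
            raise ModelValidationError("free-flux basis construction failed (rank defect)")
        for i, j in enumerate(dep_idx):
            T[j, :] = coeffs[i, :]
    return FreeFluxBasis(net, [rxn_ids[j] for j in free_idx], T)


def steady_state_residual(net: MetabolicNetwork, flux: FluxState) -> float:
    """Max absolute imbalance of S v relative to the flux scale."""
    S, _ = stoichiometric_matrix(net)
    v = flux.net_vector(net.reaction_ids)
    scale = max(1.0, float(np.max(np.abs(v))))
    if S.size == 0:
        return 0.0
    return float(np.max(np.abs(S @ v)) / scale)


def network_summary(net: MetabolicNetwork, basis: FreeFluxBasis | None = None) -> str:
    """JSON summary: counts and validation status."""
    info = {
        "n_reactions": len(net.reactions),
        "n_balanced_metabolites": len(net.balanced_metabolites),
        "n_substrates": len(net.substrates),
        "n_sinks": len(net.sinks),
        "n_reversible": sum(r.reversible for r in net.reactions),
    }
    if basis is not None:
        info["n_free_fluxes"] = basis.n_free
    return json.dumps(info, indent=2, sort_keys=True)
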
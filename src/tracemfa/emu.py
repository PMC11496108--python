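"""Steady-state mass-isotopomer simulation via EMU decomposition.

An EMU (elementary metabolite unit) is a subset of a metabolite's carbon
atoms. The isotope-labeling state of the network at steady state is obtained
by solving, for each EMU size in increasing order, a linear balance system
``A X = B`` whose unknowns are the MIDs of same-size EMUs and whose right-hand
side collects substrate EMUs and convolutions of smaller EMUs.

Reversible reactions are expanded to forward/backward flux pairs
``f = max(net, 0) + exch`` and ``b = max(-net, 0) + exch`` before assembly.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .model_io import FluxState, MetabolicNetwork

__all__ = [
    "EMU",
    "SubstrateLabeling",
    "MixtureSpec",
    "SimulationError",
    "UnreachableEMUError",
    "emu_decompose",
    "simulate_mids",
    "mix_mids",
    "spent_medium_mid",
    "orientation_fluxes",
    "oriented_reactions",
    "validate_mid",
]

_PRUNE_TOL = 1e-12


class SimulationError(RuntimeError):
    pass


class UnreachableEMUError(SimulationError):
    pass


@dataclass(frozen=True, order=True)
class EMU:
    met: str
    atoms: tuple[int, ...]  # sorted, 1-based

    def __post_init__(self):
        object.__setattr__(self, "atoms", tuple(sorted(self.atoms)))
        if len(set(self.atoms)) != len(self.atoms) or any(a < 1 for a in self.atoms):
            raise ValueError(f"invalid atom index set {self.atoms}")

    @property
    def size(self) -> int:
        return len(self.atoms)

    def __repr__(self):
        return f"{self.met}{{{','.join(map(str, self.atoms))}}}"


class SubstrateLabeling:
    """Per-atom 13C probabilities for every network substrate.

    Atoms are assumed independently labeled, which covers the designs used
    here (uniform tracer purity, fully labeled, unlabeled). MIDs of arbitrary
    atom subsets are then convolutions of per-atom Bernoulli distributions.
    """

    def __init__(self, positional: dict[str, np.ndarray]):
        self.positional = {m: np.asarray(p, dtype=float) for m, p in positional.items()}
        for m, p in self.positional.items():
            if np.any(p < 0) or np.any(p > 1):
                raise ValueError(f"substrate {m}: enrichment outside [0, 1]")

    @classmethod
    def uniform(cls, spec: dict[str, tuple[int, float]]) -> "SubstrateLabeling":
        """Build from ``{met: (n_carbons, enrichment)}``."""
        return cls({m: np.full(n, e) for m, (n, e) in spec.items()})

    def covers(self, substrates) -> bool:
        return set(substrates) <= set(self.positional)

    def emu_mid(self, emu: EMU) -> np.ndarray:
        p = self.positional[emu.met]
        mid = np.array([1.0])
        for a in emu.atoms:
            mid = np.convolve(mid, [1.0 - p[a - 1], p[a - 1]])
        return mid

    def mid(self, met: str) -> np.ndarray:
        n = len(self.positional[met])
        return self.emu_mid(EMU(met, tuple(range(1, n + 1))))


@dataclass
class MixtureSpec:
    """A measured pool modelled as a convex mixture of components.

    Components are metabolite ids simulated from the network, except ids
    present in ``fixed_mids`` (e.g. a fresh-medium reference), whose MIDs are
    constants.
    """

    id: str
    components: list[str]
    fixed_mids: dict[str, np.ndarray] = field(default_factory=dict)


# ---------------------------------------------------------------------------
# flux expansion


def oriented_reactions(net: MetabolicNetwork):
    """Yield (rxn, direction, substrate_terms, product_terms) orientations."""
    for r in net.reactions:
        yield r, "f", r.substrates, r.products
        if r.reversible:
            yield r, "b", r.products, r.substrates


def orientation_fluxes(net: MetabolicNetwork, flux: FluxState, tol: float = 1e-9):
    """Non-negative flux of each reaction orientation.

    Raises :class:`SimulationError` for significantly negative irreversible
    fluxes; values within ``-tol * scale`` are clipped to zero.
    """
    scale = max(1.0, max((abs(v) for v in flux.net_flux.values()), default=1.0))
    out: dict[tuple[str, str], float] = {}
    for r in net.reactions:
        v = flux.net_flux[r.id]
        if r.reversible:
            exch = flux.exchange_flux.get(r.id, 0.0)
            if exch < -tol * scale:
                raise SimulationError(f"reaction {r.id}: negative exchange flux {exch}")
            exch = max(exch, 0.0)
            out[(r.id, "f")] = max(v, 0.0) + exch
            out[(r.id, "b")] = max(-v, 0.0) + exch
        else:
            if v < -tol * scale:
                raise SimulationError(f"reaction {r.id}: negative irreversible flux {v}")
            out[(r.id, "f")] = max(v, 0.0)
    return out


# ---------------------------------------------------------------------------
# decomposition


@dataclass(frozen=True)
class Production:
    rxn_id: str
    direction: str
    sources: tuple[EMU, ...]  # >1 entries means convolution


@dataclass
class EMUGraph:
    productions: dict[EMU, tuple[Production, ...]]
    inputs: set[EMU]  # substrate EMUs with labeling-defined MIDs
    targets: tuple[EMU, ...]

    @property
    def levels(self) -> dict[int, list[EMU]]:
        out: dict[int, list[EMU]] = {}
        for e in self.productions:
            out.setdefault(e.size, []).append(e)
        return {s: sorted(v) for s, v in sorted(out.items())}


def _target_emu(net: MetabolicNetwork, target) -> EMU:
    if isinstance(target, EMU):
        return target
    n = net.n_carbons(target)
    if n == 0:
        raise KeyError(f"unknown or carbon-free metabolite {target!r}")
    return EMU(target, tuple(range(1, n + 1)))


def emu_decompose(net: MetabolicNetwork, targets) -> EMUGraph:
    """Predecessor closure of the target EMUs through the atom maps."""
    target_emus = tuple(_target_emu(net, t) for t in targets)
    productions: dict[EMU, tuple[Production, ...]] = {}
    inputs: set[EMU] = set()
    stack = list(target_emus)
    orientations = list(oriented_reactions(net))
    while stack:
        emu = stack.pop()
        if emu in productions or emu in inputs:
            continue
        if emu.met in net.substrates:
            inputs.add(emu)
            continue
        prods = []
        for rxn, direction, subs, prods_terms in orientations:
            for pterm in prods_terms:
                if pterm.met != emu.met or pterm.atoms is None:
                    continue
                letters = {pterm.atoms[i - 1] for i in emu.atoms}
                sources = []
                found = set()
                for sterm in subs:
                    if sterm.atoms is None:
                        continue
                    idx = tuple(
                        j + 1 for j, ch in enumerate(sterm.atoms) if ch in letters
                    )
                    if idx:
                        sources.append(EMU(sterm.met, idx))
                        found.update(sterm.atoms[j - 1] for j in idx)
                if found != letters:
                    raise SimulationError(
                        f"reaction {rxn.id}: atoms {letters - found} of {emu} "
                        f"have no substrate origin"
                    )
                prods.append(Production(rxn.id, direction, tuple(sorted(sources))))
                stack.extend(sources)
        if not prods:
            raise UnreachableEMUError(f"{emu}: no producing reaction")
        productions[emu] = tuple(prods)
    return EMUGraph(productions, inputs, target_emus)


# ---------------------------------------------------------------------------
# simulation


def validate_mid(mid: np.ndarray, tol: float = 1e-9, what: str = "MID") -> np.ndarray:
    mid = np.asarray(mid, dtype=float)
    if np.any(mid < -tol):
        raise SimulationError(f"{what}: negative fraction {mid.min()}")
    if abs(mid.sum() - 1.0) > max(tol, 1e-9):
        raise SimulationError(f"{what}: fractions sum to {mid.sum()}")
    return np.clip(mid, 0.0, None)


def simulate_mids(
    net: MetabolicNetwork,
    flux: FluxState,
    labeling: SubstrateLabeling,
    targets,
    graph: EMUGraph | None = None,
    flux_tol: float = 1e-9,
    warn_pruned: bool = True,
) -> dict:
    """Simulate steady-state MIDs of the targets (metabolite ids or EMUs).

    ``graph`` may be passed to reuse a decomposition across flux vectors.
    """
    if not labeling.covers(net.substrates):
        missing = set(net.substrates) - set(labeling.positional)
        raise SimulationError(f"labeling missing for substrates: {sorted(missing)}")
    if graph is None:
        graph = emu_decompose(net, targets)
    ofl = orientation_fluxes(net, flux, flux_tol)

    solved: dict[EMU, np.ndarray] = {}

    def known_mid(emu: EMU) -> np.ndarray:
        if emu.met in net.substrates:
            return labeling.emu_mid(emu)
        return solved[emu]

    pruned: set[EMU] = set()
    for size, emus in graph.levels.items():
        index = {e: i for i, e in enumerate(emus)}
        n = len(emus)
        A = np.zeros((n, n))
        B = np.zeros((n, size + 1))
        for e in emus:
            i = index[e]
            total = 0.0
            for prod in graph.productions[e]:
                f = ofl[(prod.rxn_id, prod.direction)]
                if f <= _PRUNE_TOL:
                    continue
                total += f
                if len(prod.sources) == 1 and prod.sources[0] in index:
                    A[i, index[prod.sources[0]]] -= f
                else:
                    mid = known_mid(prod.sources[0])
                    for s in prod.sources[1:]:
                        mid = np.convolve(mid, known_mid(s))
                    B[i] += f * mid
            if total <= _PRUNE_TOL:
                # dead pool: zero throughput cannot influence targets at
                # steady state; see module design notes
                pruned.add(e)
                A[i] = 0.0
                A[i, i] = 1.0
                B[i] = 0.0
            else:
                A[i, i] += total
        try:
            X = np.linalg.solve(A, B)
        except np.linalg.LinAlgError as err:
            raise SimulationError(f"singular EMU balance system at size {size}: {err}")
        for e, i in index.items():
            solved[e] = np.zeros(size + 1) if e in pruned else X[i]

    if pruned and warn_pruned:
        warnings.warn(f"pruned {len(pruned)} zero-throughput EMU pool(s)", stacklevel=2)
    out = {}
    for orig, emu in zip(targets, graph.targets):
        if emu.met in net.substrates:
            mid = labeling.emu_mid(emu)
        else:
            if emu in pruned:
                raise SimulationError(f"target {emu} fed only by zero-throughput pools")
            mid = solved[emu]
        out[orig] = validate_mid(mid, tol=1e-7, what=str(emu))
    return out


# ---------------------------------------------------------------------------
# mixtures


def mix_mids(components, weights) -> np.ndarray:
    """Elementwise convex combination of MIDs with equal carbon counts."""
    comps = [np.asarray(c, dtype=float) for c in components]
    w = np.asarray(weights, dtype=float)
    if len(comps) != len(w):
        raise ValueError("component/weight length mismatch")
    lengths = {len(c) for c in comps}
    if len(lengths) != 1:
        raise ValueError(f"mismatched carbon counts in mixture: {sorted(lengths)}")
    if np.any(w < -1e-9) or abs(w.sum() - 1.0) > 1e-9:
        raise ValueError(f"mixture weights not convex: {w}")
    out = np.zeros(lengths.pop())
    for c, wi in zip(comps, w):
        out += wi * c
    return out


def spent_medium_mid(fresh: np.ndarray, intracellular: np.ndarray, alpha: float) -> np.ndarray:
    """Pseudo-steady-state spent-medium MID: alpha*fresh + (1-alpha)*intracellular."""
    if not 0.0 <= alpha <= 1.0:
        raise ValueError(f"alpha must be in [0, 1], got {alpha}")
    return mix_mids([fresh, intracellular], [alpha, 1.0 - alpha])


def resolve_mixture_mid(
    spec: MixtureSpec, weights: np.ndarray, simulated: dict[str, np.ndarray]
) -> np.ndarray:
    comps = []
    for c in spec.components:
        if c in spec.fixed_mids:
            comps.append(spec.fixed_mids[c])
        else:
            comps.append(simulated[c])
    return mix_mids(comps, weights)


def load_labeling_config(data: dict) -> SubstrateLabeling:
    """Build a SubstrateLabeling from a parsed YAML/JSON mapping.

    Each entry is either ``{n: int, enrichment: float}`` (uniform across
    atoms, optionally scaled by ``purity``) or ``{positions: [p1, ...]}``.
    """
    positional = {}
    for met, spec in data.items():
        if "positions" in spec:
            positional[met] = np.asarray(spec["positions"], dtype=float)
        else:
            e = float(spec["enrichment"]) * float(spec.get("purity", 1.0))
            positional[met] = np.full(int(spec["n"]), e)
    return SubstrateLabeling(positional)
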
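"""Full-isotopomer reference simulator.

Solves the steady-state isotope balance on the complete isotopomer space
(2**n states per n-carbon metabolite) by Gauss-Seidel fixed-point iteration,
with no EMU decomposition. Exponential in carbon count, so only suitable for
small networks; used as an independent cross-check of the EMU engine.
"""

from __future__ import annotations

import numpy as np

from .emu import SimulationError, SubstrateLabeling, orientation_fluxes, oriented_reactions
from .model_io import FluxState, MetabolicNetwork

__all__ = ["simulate_isotopomers", "isotopomer_mids"]

_PRUNE_TOL = 1e-12


def _substrate_dist(probs: np.ndarray) -> np.ndarray:
    """Joint isotopomer distribution with independent atoms (bit k-1 = atom k)."""
    dist = np.array([1.0])
    for p in probs:
        dist = np.concatenate([dist * (1.0 - p), dist * p])
    return dist


def _marginal(dist: np.ndarray, n: int, atoms: tuple[int, ...]) -> np.ndarray:
    """Marginal distribution over a subset of atoms (1-based), in atom order."""
    k = len(atoms)
    out = np.zeros(1 << k)
    for pattern in range(len(dist)):
        sub = 0
        for b, a in enumerate(atoms):
            if pattern >> (a - 1) & 1:
                sub |= 1 << b
        out[sub] += dist[pattern]
    return out


def simulate_isotopomers(
    net: MetabolicNetwork,
    flux: FluxState,
    labeling: SubstrateLabeling,
    tol: float = 1e-13,
    max_iter: int = 100000,
) -> dict[str, np.ndarray]:
    """Isotopomer distributions of all carbon-carrying non-substrate pools."""
    ofl = orientation_fluxes(net, flux)
    mets = sorted(
        m for m, n in net.carbon_counts.items() if n > 0 and m not in net.substrates
    )
    ncarb = net.carbon_counts

    # production events: (target met, flux key, [(source met, source atoms,
    # product bit positions)])
    events: dict[str, list] = {m: [] for m in mets}
    for rxn, direction, subs, prods in oriented_reactions(net):
        for pterm in prods:
            if pterm.met not in events or pterm.atoms is None:
                continue
            letter_pos = {ch: i for i, ch in enumerate(pterm.atoms)}  # bit index
            parts = []
            for sterm in subs:
                if sterm.atoms is None:
                    continue
                src_atoms = []
                bits = []
                for j, ch in enumerate(sterm.atoms):
                    if ch in letter_pos:
                        src_atoms.append(j + 1)
                        bits.append(letter_pos[ch])
                if src_atoms:
                    parts.append((sterm.met, tuple(src_atoms), tuple(bits)))
            events[pterm.met].append(((rxn.id, direction), parts))

    dists: dict[str, np.ndarray] = {}
    for m in mets:
        d = np.zeros(1 << ncarb[m])
        d[0] = 1.0
        dists[m] = d
    sub_dists = {m: _substrate_dist(labeling.positional[m]) for m in net.substrates}

    def source_dist(met):
        return sub_dists[met] if met in sub_dists else dists[met]

    for _ in range(max_iter):
        delta = 0.0
        for m in mets:
            total = 0.0
            acc = np.zeros(1 << ncarb[m])
            for key, parts in events[m]:
                f = ofl[key]
                if f <= _PRUNE_TOL:
                    continue
                total += f
                contrib = np.ones(1)
                placed_bits: list[int] = []
                for src_met, src_atoms, bits in parts:
                    marg = _marginal(source_dist(src_met), ncarb.get(src_met, 0), src_atoms)
                    new = np.zeros(len(contrib) * len(marg))
                    # interleave: existing placed bits stay, new bits appended
                    for sp in range(len(marg)):
                        new[sp * len(contrib):(sp + 1) * len(contrib)] = contrib * marg[sp]
                    contrib = new
                    placed_bits.extend(bits)
                # reorder from placement order to product bit order
                full = np.zeros(1 << ncarb[m])
                for packed in range(len(contrib)):
                    pattern = 0
                    for k, b in enumerate(placed_bits):
                        if packed >> k & 1:
                            pattern |= 1 << b
                    full[pattern] += contrib[packed]
                acc += f * full
            if total <= _PRUNE_TOL:
                continue  # dead pool, keep unlabeled placeholder
            new_d = acc / total
            delta = max(delta, float(np.max(np.abs(new_d - dists[m]))))
            dists[m] = new_d
        if delta < tol:
            return dists
    raise SimulationError(f"isotopomer fixed point did not converge (last delta {delta})")


def isotopomer_mids(
    net: MetabolicNetwork,
    flux: FluxState,
    labeling: SubstrateLabeling,
    targets: list[str],
    **kwargs,
) -> dict[str, np.ndarray]:
    """MIDs of target metabolites from the full isotopomer solution."""
    dists = simulate_isotopomers(net, flux, labeling, **kwargs)
    out = {}
    for m in targets:
        if m in net.substrates:
            out[m] = labeling.mid(m)
            continue
        n = net.carbon_counts[m]
        d = dists[m]
        mid = np.zeros(n + 1)
        for pattern, p in enumerate(d):
            mid[bin(pattern).count("1")] += p
        out[m] = mid
    return out
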
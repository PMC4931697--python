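"""Steady-state labelling simulation via EMU decomposition.

An EMU (elementary metabolite unit) is a metabolite together with an
ordered subset of its carbon atoms; it is the minimal state variable
needed to simulate mass isotopomer distributions (MIDs).  Working
backwards from target EMUs through the atom maps yields a layered EMU
reaction network in which every EMU's precursors are either boundary
(source/pool) EMUs or EMUs of equal or smaller size; condensation
reactions appear as convolution nodes.  The cascade is solved size by
size with dense linear solves — the networks here are tiny.

Reversible reactions are split into forward/backward unidirectional
reactions with effective fluxes max(v,0)+e and max(-v,0)+e.  Rotationally
symmetric metabolites (succinate, fumarate) are averaged 50/50 over the
two atom orientations by splitting every producing route.

A full positional-isotopomer fixed-point solver
(:func:`brute_force_isotopomer_oracle`) provides an independent check of
the EMU cascade on networks small enough to enumerate 2^n isotopomer
states per metabolite.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import product as iter_product

import numpy as np
from scipy.linalg import lu_factor, lu_solve

from .fluxes import FluxState
from .network_model import NetworkModel

__all__ = [
    "EMU",
    "LabelInput",
    "ExpandedReaction",
    "EMUNetwork",
    "SteadyStateSolver",
    "LabellingError",
    "expand_reactions",
    "emu_decompose",
    "solve_steady_state_mids",
    "brute_force_isotopomer_oracle",
    "collapse_to_mid",
    "validate_mid",
]

MID_SUM_TOL = 1e-9
MID_NEG_TOL = 1e-12


class LabellingError(RuntimeError):
    """Raised for unsolvable labelling systems (unreached EMUs, bad fluxes)."""


@dataclass(frozen=True, order=True)
class EMU:
    """A metabolite with a strictly increasing, 1-based subset of its atoms."""

    metabolite: str
    atoms: tuple[int, ...]

    def __post_init__(self):
        if not self.atoms:
            raise ValueError("EMU needs at least one atom")
        if any(b <= a for a, b in zip(self.atoms, self.atoms[1:])):
            raise ValueError("EMU atom indices must be strictly increasing")

    @property
    def size(self) -> int:
        return len(self.atoms)

    def __repr__(self):  # compact, e.g. PYR_c[1,2,3]
        return f"{self.metabolite}[{','.join(map(str, self.atoms))}]"


def validate_mid(mid: np.ndarray, where: str = "") -> np.ndarray:
    """Clip tiny negatives, check normalisation; returns the cleaned MID."""
    mid = np.asarray(mid, dtype=float)
    if mid.min() < -1e-8:
        raise LabellingError(f"negative MID component {mid.min():.3g} {where}")
    mid = np.where(mid < 0, 0.0, mid)
    s = mid.sum()
    if abs(s - 1.0) > 1e-6:
        raise LabellingError(f"MID sums to {s:.6g} {where}")
    return mid / s


# ---------------------------------------------------------------------------
# label inputs


class LabelInput:
    """Positional isotopomer distributions of boundary metabolites.

    Stores, per fixed-source or accumulating-pool metabolite, the full
    2^n distribution over positional labelling states (bit i-1 of the
    state index = atom i labelled).  EMU MIDs of any atom subset are
    marginals of this distribution.
    """

    def __init__(self, positional: dict[str, np.ndarray]):
        self.positional: dict[str, np.ndarray] = {}
        for met, dist in positional.items():
            dist = np.asarray(dist, dtype=float)
            n = int(np.log2(len(dist)))
            if 2**n != len(dist):
                raise ValueError(f"{met}: positional distribution length not 2^n")
            if abs(dist.sum() - 1.0) > 1e-9 or dist.min() < -MID_NEG_TOL:
                raise ValueError(f"{met}: positional distribution not normalised")
            self.positional[met] = np.clip(dist, 0.0, None)
        self._cache: dict[EMU, np.ndarray] = {}

    @staticmethod
    def pattern_distribution(n: int, pattern, natural_p: float = 0.0) -> np.ndarray:
        """Positional distribution of one labelling pattern.

        ``pattern`` is "U" (uniformly 13C), "0"/"unlabelled" (12C at
        every position, or independent natural 13C if ``natural_p`` > 0),
        or a bitstring like "110" (atom 1 and 2 labelled).
        """
        dist = np.zeros(2**n)
        if isinstance(pattern, str) and pattern.upper() == "U":
            dist[2**n - 1] = 1.0
            return dist
        if pattern in ("0", "unlabelled", "natural"):
            if natural_p > 0.0:
                for s in range(2**n):
                    k = bin(s).count("1")
                    dist[s] = natural_p**k * (1 - natural_p) ** (n - k)
            else:
                dist[0] = 1.0
            return dist
        bits = str(pattern)
        if len(bits) != n or set(bits) - {"0", "1"}:
            raise ValueError(f"bad labelling pattern {pattern!r} for {n} carbons")
        s = sum(1 << i for i, b in enumerate(bits) if b == "1")
        dist[s] = 1.0
        return dist

    @classmethod
    def from_patterns(cls, model: NetworkModel,
                      spec: dict[str, list[tuple[float, str]]],
                      natural_p: float = 0.0) -> "LabelInput":
        """Build inputs from mixtures, e.g. {"GLC_x": [(0.469, "U"), (0.531, "0")]}."""
        positional = {}
        for met, mixture in spec.items():
            n = model.metabolites[met].carbon_count
            dist = np.zeros(2**n)
            total = 0.0
            for frac, pattern in mixture:
                dist += frac * cls.pattern_distribution(n, pattern, natural_p)
                total += frac
            if abs(total - 1.0) > 1e-9:
                raise ValueError(f"{met}: mixture fractions sum to {total}")
            positional[met] = dist
        return cls(positional)

    def emu_mid(self, emu: EMU) -> np.ndarray:
        if emu not in self._cache:
            try:
                dist = self.positional[emu.metabolite]
            except KeyError:
                raise LabellingError(
                    f"no label input for boundary metabolite {emu.metabolite}"
                ) from None
            self._cache[emu] = marginal_mid(dist, emu.atoms)
        return self._cache[emu]


def marginal_mid(dist: np.ndarray, atoms: tuple[int, ...]) -> np.ndarray:
    """MID of an atom subset from a full positional distribution."""
    n = int(np.log2(len(dist)))
    states = np.arange(len(dist))
    k = np.zeros(len(dist), dtype=int)
    for a in atoms:
        k += (states >> (a - 1)) & 1
    return np.bincount(k, weights=dist, minlength=len(atoms) + 1)


def collapse_to_mid(dist: np.ndarray, n: int) -> np.ndarray:
    """Collapse a 2^n positional distribution to its M0..Mn MID."""
    return marginal_mid(dist, tuple(range(1, n + 1)))


# ---------------------------------------------------------------------------
# unidirectional expansion


@dataclass(frozen=True)
class ExpandedReaction:
    """One unidirectional, orientation-resolved reaction instance."""

    rid: str
    direction: int  # +1 forward, -1 backward
    weight: float  # orientation weight, (1/2)^k for k symmetric products
    substrates: tuple[tuple[str, tuple[str, ...] | None], ...]
    products: tuple[tuple[str, tuple[str, ...] | None], ...]

    def flux(self, fluxes: FluxState) -> float:
        f = fluxes.forward(self.rid) if self.direction > 0 else fluxes.backward(self.rid)
        return self.weight * f


def expand_reactions(model: NetworkModel) -> list[ExpandedReaction]:
    """Split reversible reactions and average symmetric-product orientations."""
    out: list[ExpandedReaction] = []
    for r in model.reactions:
        sides = [(1, r.substrates, r.products)]
        if r.reversible:
            sides.append((-1, r.products, r.substrates))
        for direction, subs, prods in sides:
            subs_t = tuple((t.metabolite, t.atom_map) for t in subs)
            prods_t = tuple((t.metabolite, t.atom_map) for t in prods)
            sym_idx = [
                i for i, (met, amap) in enumerate(prods_t)
                if met in model.symmetric and amap is not None
            ]
            for flips in iter_product((False, True), repeat=len(sym_idx)):
                prods_v = list(prods_t)
                for i, flip in zip(sym_idx, flips):
                    if flip:
                        met, amap = prods_v[i]
                        prods_v[i] = (met, tuple(reversed(amap)))
                weight = 0.5 ** len(sym_idx)
                out.append(
                    ExpandedReaction(r.id, direction, weight, subs_t, tuple(prods_v))
                )
    return out


# ---------------------------------------------------------------------------
# EMU decomposition


@dataclass
class EMUNetwork:
    """Layered EMU network: balanced-EMU nodes with their producing routes.

    Each route is ``(expanded_reaction_index, (source EMU, ...))``; more
    than one source means a convolution (condensation) node.
    """

    model: NetworkModel
    expanded: list[ExpandedReaction]
    nodes: dict[EMU, list[tuple[int, tuple[EMU, ...]]]]
    inputs: set[EMU]
    targets: list[EMU]

    @property
    def sizes(self) -> list[int]:
        return sorted({e.size for e in self.nodes})

    def edge_table(self):
        """Debug dump: one row per route edge (tab-friendly tuples)."""
        rows = []
        for emu, routes in sorted(self.nodes.items()):
            for idx, sources in routes:
                er = self.expanded[idx]
                rows.append(
                    (repr(emu), er.rid, er.direction, er.weight,
                     " + ".join(map(repr, sources)))
                )
        return rows


def emu_decompose(model: NetworkModel, targets) -> EMUNetwork:
    """Backward-trace target EMUs through the atom maps.

    Raises :class:`LabellingError` if a target sits on a metabolite with
    no producing path or an atom cannot be traced to any substrate.
    """
    targets = [t if isinstance(t, EMU) else _full_emu(model, t) for t in targets]
    expanded = expand_reactions(model)
    nodes: dict[EMU, list[tuple[int, tuple[EMU, ...]]]] = {}
    inputs: set[EMU] = set()
    stack = list(targets)
    while stack:
        emu = stack.pop()
        role = model.metabolites[emu.metabolite].role
        if role != "balanced":
            inputs.add(emu)
            continue
        if emu in nodes:
            continue
        routes = []
        for idx, er in enumerate(expanded):
            for met, letters in er.products:
                if met != emu.metabolite or letters is None:
                    continue
                needed = {letters[a - 1] for a in emu.atoms}
                sources = []
                found = 0
                for smet, sletters in er.substrates:
                    if sletters is None:
                        continue
                    atoms = tuple(
                        i + 1 for i, c in enumerate(sletters) if c in needed
                    )
                    if atoms:
                        sources.append(EMU(smet, atoms))
                        found += len(atoms)
                if found != len(needed):
                    raise LabellingError(
                        f"{er.rid}: atoms of {emu!r} cannot be traced to substrates"
                    )
                routes.append((idx, tuple(sources)))
                stack.extend(sources)
        if not routes:
            raise LabellingError(f"{emu!r} has no producing reaction")
        nodes[emu] = routes
    return EMUNetwork(model, expanded, nodes, inputs, targets)


def _full_emu(model: NetworkModel, met: str) -> EMU:
    n = model.metabolites[met].carbon_count
    return EMU(met, tuple(range(1, n + 1)))


# ---------------------------------------------------------------------------
# cascade solver


class SteadyStateSolver:
    """Solves the EMU cascade for given fluxes; reusable across inputs.

    The balance matrices depend only on the fluxes, so :meth:`prepare`
    LU-factorises them once and the returned cascade re-solves cheaply
    for every new set of boundary MIDs (the inner loop of the hybrid
    integrator).
    """

    def __init__(self, network: EMUNetwork):
        self.network = network
        self.levels = []
        for size in network.sizes:
            unknowns = sorted(e for e in network.nodes if e.size == size)
            index = {e: i for i, e in enumerate(unknowns)}
            internal, external = [], []
            for e in unknowns:
                for idx, sources in network.nodes[e]:
                    if (
                        len(sources) == 1
                        and sources[0] in network.nodes
                        and sources[0].size == size
                    ):
                        internal.append((index[e], index[sources[0]], idx))
                    else:
                        external.append((index[e], idx, sources))
            self.levels.append((size, unknowns, internal, external))

    def prepare(self, fluxes: FluxState) -> "PreparedCascade":
        for r in self.network.model.reactions:
            if not r.reversible and fluxes.net.get(r.id, 0.0) < -1e-12:
                raise LabellingError(
                    f"negative effective flux on irreversible reaction {r.id}"
                )
        prepared = []
        for size, unknowns, internal, external in self.levels:
            n = len(unknowns)
            A = np.zeros((n, n))
            fluxes_ext = []
            # diagonal: total production into each EMU's metabolite pool
            for i, e in enumerate(unknowns):
                total = sum(
                    self.network.expanded[idx].flux(fluxes)
                    for idx, _ in self.network.nodes[e]
                )
                if total <= 0:
                    raise LabellingError(f"{e!r} is unreached (zero influx)")
                A[i, i] = total
            for i, j, idx in internal:
                A[i, j] -= self.network.expanded[idx].flux(fluxes)
            for i, idx, sources in external:
                fluxes_ext.append((i, self.network.expanded[idx].flux(fluxes), sources))
            try:
                lu = lu_factor(A)
            except Exception as exc:  # pragma: no cover - defensive
                raise LabellingError(f"singular EMU balance at size {size}") from exc
            prepared.append((size, unknowns, lu, fluxes_ext))
        return PreparedCascade(self.network, prepared)


class PreparedCascade:
    def __init__(self, network, prepared):
        self.network = network
        self._prepared = prepared

    def solve(self, input_mids) -> dict[EMU, np.ndarray]:
        """Solve the cascade; ``input_mids`` maps boundary EMU -> MID.

        ``input_mids`` may be a :class:`LabelInput` or any object with an
        ``emu_mid(emu)`` method / a plain dict.
        """
        get = _mid_getter(input_mids)
        mids: dict[EMU, np.ndarray] = {}

        def source_mid(emu: EMU) -> np.ndarray:
            if emu in mids:
                return mids[emu]
            return get(emu)

        for size, unknowns, lu, external in self._prepared:
            rhs = np.zeros((len(unknowns), size + 1))
            for i, f, sources in external:
                vec = source_mid(sources[0])
                for s in sources[1:]:
                    vec = np.convolve(vec, source_mid(s))
                rhs[i] += f * vec
            X = lu_solve(lu, rhs)
            for i, e in enumerate(unknowns):
                mids[e] = validate_mid(X[i], where=repr(e))
        return mids


def _mid_getter(input_mids):
    if hasattr(input_mids, "emu_mid"):
        return input_mids.emu_mid
    return input_mids.__getitem__


def solve_steady_state_mids(model: NetworkModel, fluxes: FluxState,
                            inputs, targets) -> dict[EMU, np.ndarray]:
    """One-shot convenience: decompose, prepare and solve for `targets`.

    ``targets`` may mix EMUs and metabolite names (full-carbon EMUs).
    Requires S·v_net = 0 (checked) and non-negative effective fluxes.
    """
    fluxes.check_balance(model)
    net = emu_decompose(model, targets)
    cascade = SteadyStateSolver(net).prepare(fluxes)
    mids = cascade.solve(inputs)
    out = {}
    for t in net.targets:
        out[t] = mids[t]
    return out


# ---------------------------------------------------------------------------
# full-isotopomer oracle


def brute_force_isotopomer_oracle(model: NetworkModel, fluxes: FluxState,
                                  inputs: LabelInput, tol: float = 1e-13,
                                  max_sweeps: int = 200_000) -> dict[str, np.ndarray]:
    """Steady-state MIDs of all balanced metabolites by positional fixed point.

    Solves the full positional-isotopomer balance by Gauss–Seidel
    iteration on the flux-weighted mixing map (a contraction for any
    well-posed network) and collapses to MIDs.  Independent of the EMU
    machinery except for the shared unidirectional expansion.
    """
    expanded = expand_reactions(model)
    balanced = model.balanced_metabolites
    ncarb = {m: model.metabolites[m].carbon_count for m in model.metabolites}
    # producing routes per balanced metabolite
    routes: dict[str, list] = {m: [] for m in balanced}
    for idx, er in enumerate(expanded):
        for occ, (met, letters) in enumerate(er.products):
            if met in routes and letters is not None:
                routes[met].append((idx, _compile_route(er, letters)))
    for m in balanced:
        if not routes[m]:
            raise LabellingError(f"{m} has no producing reaction")

    state: dict[str, np.ndarray] = {}
    for m in balanced:
        state[m] = np.zeros(2 ** ncarb[m])
        state[m][0] = 1.0

    def dist_of(met: str) -> np.ndarray:
        if met in state:
            return state[met]
        try:
            return inputs.positional[met]
        except KeyError:
            raise LabellingError(f"no label input for {met}") from None

    flux_cache = [er.flux(fluxes) for er in expanded]
    for sweep in range(max_sweeps):
        delta = 0.0
        for m in balanced:
            total = 0.0
            acc = np.zeros(2 ** ncarb[m])
            for idx, compiled in routes[m]:
                f = flux_cache[idx]
                if f <= 0:
                    continue
                acc += f * _route_dist(compiled, dist_of, ncarb[m])
                total += f
            if total <= 0:
                raise LabellingError(f"{m} is unreached (zero influx)")
            new = acc / total
            delta = max(delta, float(np.max(np.abs(new - state[m]))))
            state[m] = new
        if delta < tol:
            break
    else:
        raise LabellingError("isotopomer fixed point did not converge")
    return {m: collapse_to_mid(state[m], ncarb[m]) for m in balanced}


def _compile_route(er: ExpandedReaction, prod_letters):
    """Per substrate: index array mapping substrate states to product bit masks."""
    letter_to_ppos = {c: i for i, c in enumerate(prod_letters)}
    compiled = []
    for smet, sletters in er.substrates:
        if sletters is None:
            continue
        pairs = [
            (spos, letter_to_ppos[c])
            for spos, c in enumerate(sletters)
            if c in letter_to_ppos
        ]
        if not pairs:
            continue
        ns = len(sletters)
        states = np.arange(2**ns)
        contrib = np.zeros(2**ns, dtype=np.int64)
        for spos, ppos in pairs:
            contrib |= ((states >> spos) & 1) << ppos
        compiled.append((smet, contrib))
    return compiled


def _route_dist(compiled, dist_of, n_prod: int) -> np.ndarray:
    out = None
    for smet, contrib in compiled:
        w = np.zeros(2**n_prod)
        np.add.at(w, contrib, dist_of(smet))
        if out is None:
            out = w
        else:  # disjoint bit masks: mask-OR equals integer addition
            flat = np.outer(out, w).ravel()
            idx = (
                np.arange(2**n_prod)[:, None] + np.arange(2**n_prod)[None, :]
            ).ravel()
            out = np.bincount(idx, weights=flat, minlength=2**n_prod)[: 2**n_prod]
    return out
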
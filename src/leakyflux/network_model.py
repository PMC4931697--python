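"""Atom-mapped metabolic network: parsing, validation and stoichiometric machinery.

The model file dialect is a tab-delimited text format in the OpenFLUX
lineage.  Each reaction line carries an identifier, a reaction equation
with inline parenthesised carbon maps, and an optional reversibility
flag::

    HK\tGLC_x (abcdef) -> G6P (abcdef)\tF
    LDH\tPYR_c (abc) <-> LAC_c (abc)

A ``<->`` arrow (or flag ``R``) marks the reaction reversible.  A second
accepted form separates equation and atom maps into their own columns
(``id\tA + B = C\tab + c = abc\tF``).  Lines starting with ``#`` are
comments; lines starting with ``@`` are directives assigning metabolite
roles::

    @source GLC_x GLN_x CO2     # fixed boundary pools (known labelling)
    @pool LAC_x PYR_x           # accumulating extracellular pools
    @symmetric SUC FUM          # rotationally symmetric carbon skeletons
    @normalize HK               # measured anchor flux

Every metabolite not declared a source or pool is treated as an
intracellular balanced metabolite (steady state).  An empty product side
(``P5P (bcde) ->``) exports carbon out of the system (a sink boundary).

Carbon maps use lower-case letters, one per carbon, unique within the
substrate side of a reaction; atom positions are 1-based and letters map
left to right.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from fractions import Fraction
from math import gcd

import numpy as np
import sympy

__all__ = [
    "NetworkError",
    "Metabolite",
    "ReactionTerm",
    "Reaction",
    "NetworkModel",
    "ElementaryMode",
    "FreeFluxBasis",
    "parse_model",
    "load_model",
    "stoichiometric_matrix",
    "free_flux_basis",
    "enumerate_elementary_modes",
]


class NetworkError(ValueError):
    """Raised for malformed or inconsistent network definitions."""


@dataclass(frozen=True)
class Metabolite:
    name: str
    carbon_count: int
    compartment: str  # "intracellular" | "extracellular"
    role: str  # "balanced" | "accumulating_pool" | "fixed_source"

    def __post_init__(self):
        if self.carbon_count < 1:
            raise NetworkError(f"{self.name}: carbon_count must be positive")
        if self.role not in ("balanced", "accumulating_pool", "fixed_source"):
            raise NetworkError(f"{self.name}: unknown metabolite role {self.role!r}")
        if self.role == "accumulating_pool" and self.compartment != "extracellular":
            raise NetworkError(
                f"{self.name}: accumulating_pool is only legal extracellularly"
            )


@dataclass(frozen=True)
class ReactionTerm:
    """One metabolite occurrence on one side of a reaction.

    Stoichiometric coefficients are always 1 per occurrence; repeated
    participation is written as repeated terms so that every occurrence
    carries its own atom map.
    """

    metabolite: str
    atom_map: tuple[str, ...] | None = None  # one letter per carbon, or None


@dataclass(frozen=True)
class Reaction:
    id: str
    substrates: tuple[ReactionTerm, ...]
    products: tuple[ReactionTerm, ...]
    reversible: bool = False

    @property
    def is_boundary(self) -> bool:
        return not self.substrates or not self.products


@dataclass
class NetworkModel:
    """A validated atom-mapped network.

    ``metabolites`` maps name -> Metabolite; ``reactions`` preserves file
    order.  ``symmetric`` names metabolites whose carbon skeleton is
    rotationally symmetric (succinate, fumarate): their labelling is
    averaged over the two atom orientations downstream.
    """

    metabolites: dict[str, Metabolite]
    reactions: list[Reaction]
    symmetric: frozenset[str] = frozenset()
    normalising_flux: str | None = None

    def metabolite(self, name: str) -> Metabolite:
        return self.metabolites[name]

    def reaction(self, rid: str) -> Reaction:
        for r in self.reactions:
            if r.id == rid:
                return r
        raise KeyError(rid)

    @property
    def balanced_metabolites(self) -> list[str]:
        return [m.name for m in self.metabolites.values() if m.role == "balanced"]

    @property
    def pools(self) -> list[str]:
        return [
            m.name for m in self.metabolites.values() if m.role == "accumulating_pool"
        ]

    @property
    def sources(self) -> list[str]:
        return [m.name for m in self.metabolites.values() if m.role == "fixed_source"]

    @property
    def reversible_reactions(self) -> list[str]:
        return [r.id for r in self.reactions if r.reversible]


_TERM_RE = re.compile(r"^([A-Za-z_]\w*)\s*(?:\(\s*([a-z]+)\s*\))?$")


def _parse_side(side: str, rid: str) -> tuple[ReactionTerm, ...]:
    side = side.strip()
    if not side:
        return ()
    terms = []
    for chunk in re.split(r"\s+\+\s+", side):
        chunk = chunk.strip()
        m = _TERM_RE.match(chunk)
        if m is None:
            if re.match(r"^\d", chunk):
                raise NetworkError(
                    f"{rid}: stoichiometric coefficients are not supported; "
                    f"repeat the term once per occurrence ({chunk!r})"
                )
            raise NetworkError(f"{rid}: cannot parse term {chunk!r}")
        name, amap = m.groups()
        terms.append(ReactionTerm(name, tuple(amap) if amap else None))
    return tuple(terms)


def _zip_maps(terms, maps, rid):
    if len(maps) != len(terms):
        raise NetworkError(f"{rid}: atom-map column does not match equation terms")
    return tuple(
        ReactionTerm(t.metabolite, tuple(m) if m not in ("", "X", "-") else None)
        for t, m in zip(terms, maps)
    )


def parse_model(text: str) -> NetworkModel:
    """Parse and validate a model file; see the module docstring for the dialect."""
    sources: set[str] = set()
    pools: set[str] = set()
    symmetric: set[str] = set()
    normalising: str | None = None
    reactions: list[Reaction] = []
    seen_ids: set[str] = set()

    for lineno, raw in enumerate(text.splitlines(), 1):
        line = raw.split("#", 1)[0].rstrip()
        if not line.strip():
            continue
        if line.lstrip().startswith("@"):
            parts = line.split()
            directive, args = parts[0][1:].lower(), parts[1:]
            if directive == "source":
                sources.update(args)
            elif directive == "pool":
                pools.update(args)
            elif directive == "symmetric":
                symmetric.update(args)
            elif directive == "normalize":
                normalising = args[0] if args else None
            else:
                raise NetworkError(f"line {lineno}: unknown directive @{directive}")
            continue

        cols = [c.strip() for c in line.split("\t") if c.strip() != ""]
        if len(cols) < 2:
            # allow "id: equation" convenience form
            if ":" in line:
                rid, eq = line.split(":", 1)
                cols = [rid.strip(), eq.strip()]
            else:
                raise NetworkError(f"line {lineno}: expected id<TAB>equation")
        rid = cols[0].rstrip(":")
        if rid in seen_ids:
            raise NetworkError(f"line {lineno}: duplicate reaction id {rid!r}")
        seen_ids.add(rid)

        eq = cols[1]
        flag = cols[-1].upper() if len(cols) > 2 and cols[-1].upper() in ("F", "R", "FR", "B") else None
        reversible = "<->" in eq or "<=>" in eq or flag in ("R", "FR", "B")
        lhs_rhs = re.split(r"<->|<=>|=>|->", eq)
        if len(lhs_rhs) != 2:
            # four-column OpenFLUX-style: id, equation with '=', atom maps with '='
            if "=" in eq and len(cols) >= 3 and "=" in cols[2]:
                lhs_rhs = eq.split("=")
                map_l, map_r = (cols[2].split("=") + [""])[:2]
                subs = _parse_side(lhs_rhs[0], rid)
                prods = _parse_side(lhs_rhs[1], rid)
                subs = _zip_maps(subs, [m.strip() for m in re.split(r"\s+\+\s+", map_l.strip())] if map_l.strip() else [], rid) if map_l.strip() else subs
                prods = _zip_maps(prods, [m.strip() for m in re.split(r"\s+\+\s+", map_r.strip())] if map_r.strip() else [], rid) if map_r.strip() else prods
                reactions.append(Reaction(rid, subs, prods, reversible))
                continue
            raise NetworkError(f"line {lineno}: reaction {rid!r} needs exactly one arrow")
        subs = _parse_side(lhs_rhs[0], rid)
        prods = _parse_side(lhs_rhs[1], rid)
        if not subs and not prods:
            raise NetworkError(f"line {lineno}: empty reaction {rid!r}")
        reactions.append(Reaction(rid, subs, prods, reversible))

    model = _build_model(reactions, sources, pools, symmetric, normalising)
    _validate(model)
    return model


def load_model(path) -> NetworkModel:
    with open(path) as fh:
        return parse_model(fh.read())


def _build_model(reactions, sources, pools, symmetric, normalising) -> NetworkModel:
    carbon_counts: dict[str, int] = {}
    mentioned: set[str] = set()
    for r in reactions:
        for term in r.substrates + r.products:
            mentioned.add(term.metabolite)
            if term.atom_map is not None:
                n = len(term.atom_map)
                prev = carbon_counts.setdefault(term.metabolite, n)
                if prev != n:
                    raise NetworkError(
                        f"{r.id}: atom map length {n} conflicts with carbon count "
                        f"{prev} of {term.metabolite}"
                    )
    for name in sorted(mentioned):
        if name not in carbon_counts:
            raise NetworkError(f"{name}: no atom map anywhere; carbon count unknown")
    for declared in sorted((sources | pools | symmetric) - mentioned):
        raise NetworkError(f"directive names unknown metabolite {declared!r}")

    # role inference for undeclared metabolites: anything without a
    # producing reaction is a fixed source, anything without a consuming
    # reaction an accumulating pool (reversible reactions count both ways)
    produced: set[str] = set()
    consumed: set[str] = set()
    for r in reactions:
        for t in r.substrates:
            consumed.add(t.metabolite)
            if r.reversible:
                produced.add(t.metabolite)
        for t in r.products:
            produced.add(t.metabolite)
            if r.reversible:
                consumed.add(t.metabolite)

    metabolites = {}
    for name in sorted(mentioned):
        if name in sources or name not in produced:
            role, comp = "fixed_source", "extracellular"
        elif name in pools or name not in consumed:
            role, comp = "accumulating_pool", "extracellular"
        else:
            role, comp = "balanced", "intracellular"
        metabolites[name] = Metabolite(name, carbon_counts[name], comp, role)

    if normalising is not None and normalising not in {r.id for r in reactions}:
        raise NetworkError(f"@normalize names unknown reaction {normalising!r}")
    return NetworkModel(metabolites, list(reactions), frozenset(symmetric), normalising)


def _validate(model: NetworkModel) -> None:
    for r in model.reactions:
        _check_atom_balance(r, model)
    produced: set[str] = set()
    consumed: set[str] = set()
    for r in model.reactions:
        for t in r.substrates:
            consumed.add(t.metabolite)
            if r.reversible:
                produced.add(t.metabolite)
        for t in r.products:
            produced.add(t.metabolite)
            if r.reversible:
                consumed.add(t.metabolite)
    for name in model.balanced_metabolites:
        if name not in produced or name not in consumed:
            raise NetworkError(
                f"balanced metabolite {name} must have at least one producing "
                f"and one consuming reaction"
            )


def _check_atom_balance(r: Reaction, model: NetworkModel) -> None:
    """Substrate carbon letters must appear exactly once across products.

    Boundary reactions (one empty side) are exempt from the bijection but
    letter uniqueness within a side is always enforced.
    """
    for side in (r.substrates, r.products):
        letters = [c for t in side if t.atom_map for c in t.atom_map]
        if len(letters) != len(set(letters)):
            raise NetworkError(f"{r.id}: repeated atom letter within one side")
    if r.is_boundary:
        return
    maps_missing = any(t.atom_map is None for t in r.substrates + r.products)
    boundary_met = any(
        model.metabolites[t.metabolite].role != "balanced"
        for t in r.substrates + r.products
    )
    if maps_missing:
        if boundary_met:
            return  # explicitly allowed for source/sink plumbing
        raise NetworkError(f"{r.id}: missing atom map on a carbon-balanced reaction")
    sub_letters = {c for t in r.substrates for c in t.atom_map}
    prod_letters = [c for t in r.products for c in t.atom_map]
    unmapped = [c for c in prod_letters if c not in sub_letters]
    if unmapped:
        raise NetworkError(f"{r.id}: product letters {unmapped} not found in substrates")
    if set(prod_letters) != sub_letters:
        missing = sorted(sub_letters - set(prod_letters))
        raise NetworkError(f"{r.id}: substrate letters {missing} unmapped in products")


# ---------------------------------------------------------------------------
# stoichiometry


def stoichiometric_matrix(model: NetworkModel) -> tuple[np.ndarray, list[str]]:
    """Integer stoichiometric matrix over balanced metabolites × reactions.

    Returns ``(S, row_names)`` with ``S[i, j]`` the net coefficient of
    balanced metabolite i in reaction j (file order).
    """
    rows = model.balanced_metabolites
    index = {m: i for i, m in enumerate(rows)}
    S = np.zeros((len(rows), len(model.reactions)), dtype=int)
    for j, r in enumerate(model.reactions):
        for t in r.substrates:
            if t.metabolite in index:
                S[index[t.metabolite], j] -= 1
        for t in r.products:
            if t.metabolite in index:
                S[index[t.metabolite], j] += 1
    return S, rows


@dataclass
class FreeFluxBasis:
    """Null-space parameterization v = N @ v_free with named free fluxes.

    Free fluxes correspond to non-pivot columns of the RREF of S, so each
    free coordinate IS one designated reaction's net flux.
    """

    matrix: np.ndarray  # (n_reactions, n_free)
    free_reactions: list[str]
    rank: int
    reaction_order: list[str]

    def expand(self, free_values: dict[str, float]) -> dict[str, float]:
        v_free = np.array([free_values[r] for r in self.free_reactions], dtype=float)
        v = self.matrix @ v_free
        return dict(zip(self.reaction_order, v))


def free_flux_basis(model: NetworkModel) -> FreeFluxBasis:
    S, _ = stoichiometric_matrix(model)
    n = S.shape[1]
    M = sympy.Matrix(S.tolist())
    rref, pivots = M.rref()
    pivots = list(pivots)
    free_cols = [j for j in range(n) if j not in pivots]
    if not free_cols:
        raise NetworkError("network admits no feasible nonzero flux (full-rank S)")
    N = np.zeros((n, len(free_cols)))
    for k, jf in enumerate(free_cols):
        N[jf, k] = 1.0
        for r, jp in enumerate(pivots):
            N[jp, k] = -float(rref[r, jf])
    rids = [r.id for r in model.reactions]
    return FreeFluxBasis(N, [rids[j] for j in free_cols], len(pivots), rids)


# ---------------------------------------------------------------------------
# elementary modes


@dataclass(frozen=True)
class ElementaryMode:
    """Support-minimal non-negative flux vector on the split network.

    ``coefficients`` maps ``(reaction_id, direction)`` with direction +1
    (forward) or -1 (backward, reversible reactions only) to a positive
    integer.  A 2-cycle mode (forward + backward of one reaction only) is
    a futile cycle and flagged so summaries can drop it.
    """

    coefficients: tuple[tuple[tuple[str, int], int], ...]

    @property
    def support(self) -> frozenset[tuple[str, int]]:
        return frozenset(k for k, _ in self.coefficients)

    @property
    def is_futile_cycle(self) -> bool:
        rids = {rid for (rid, _), _ in self.coefficients}
        dirs = {d for (_, d), _ in self.coefficients}
        return len(rids) == 1 and dirs == {1, -1}

    def net_fluxes(self, reaction_order: list[str]) -> np.ndarray:
        v = np.zeros(len(reaction_order))
        idx = {r: i for i, r in enumerate(reaction_order)}
        for (rid, d), c in self.coefficients:
            v[idx[rid]] += d * c
        return v


def _split_columns(model: NetworkModel):
    S, _ = stoichiometric_matrix(model)
    cols = []
    mats = []
    for j, r in enumerate(model.reactions):
        cols.append((r.id, 1))
        mats.append(S[:, j])
        if r.reversible:
            cols.append((r.id, -1))
            mats.append(-S[:, j])
    return cols, np.array(mats).T if mats else np.zeros((S.shape[0], 0), dtype=int)


def enumerate_elementary_modes(model: NetworkModel) -> list[ElementaryMode]:
    """Enumerate elementary flux modes by double description.

    Reversible reactions are split into forward/backward columns so every
    mode is non-negative.  Exact ``Fraction`` arithmetic keeps S·v = 0
    integer-exact; each mode is scaled to coprime integers.  Futile
    2-cycles of split reversible reactions are returned and flagged.
    """
    cols, Ssp = _split_columns(model)
    n = len(cols)
    m = Ssp.shape[0]
    # tableau rows: (ray over split reactions, residual S^T ray)
    rays = [
        (
            [Fraction(int(i == k)) for i in range(n)],
            [Fraction(int(Ssp[row, k])) for row in range(m)],
        )
        for k in range(n)
    ]
    for col in range(m):
        zero = [r for r in rays if r[1][col] == 0]
        pos = [r for r in rays if r[1][col] > 0]
        neg = [r for r in rays if r[1][col] < 0]
        new = list(zero)
        for rp in pos:
            for rn in neg:
                a, b = rp[1][col], -rn[1][col]
                ray = [a * x + b * y for x, y in zip(rn[0], rp[0])]
                res = [a * x + b * y for x, y in zip(rn[1], rp[1])]
                new.append((ray, res))
        rays = _minimal_support(new)
    modes = []
    seen = set()
    for ray, _ in rays:
        coeffs = _normalise_ray(ray)
        entries = tuple(
            (cols[i], c) for i, c in enumerate(coeffs) if c
        )
        if entries and entries not in seen:
            seen.add(entries)
            modes.append(ElementaryMode(entries))
    return modes


def _minimal_support(rays):
    supports = [frozenset(i for i, x in enumerate(r[0]) if x != 0) for r in rays]
    keep = []
    for i, r in enumerate(rays):
        if not supports[i]:
            continue
        minimal = True
        for j, s in enumerate(supports):
            if j != i and s and s < supports[i]:
                minimal = False
                break
            if j < i and s == supports[i]:
                minimal = False  # duplicate support: keep first only
                break
        if minimal:
            keep.append(r)
    return keep


def _normalise_ray(ray) -> list[int]:
    denoms = [f.denominator for f in ray if f != 0]
    if not denoms:
        return [0] * len(ray)
    lcm = 1
    for d in denoms:
        lcm = lcm * d // gcd(lcm, d)
    ints = [int(f * lcm) for f in ray]
    g = 0
    for v in ints:
        g = gcd(g, abs(v))
    return [v // g for v in ints] if g else ints
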
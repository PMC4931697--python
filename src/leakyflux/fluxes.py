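"""Flux state: net and exchange fluxes, reversibility ratios.

For a reversible reaction with net flux v and exchange flux e >= 0 the
effective unidirectional fluxes are

    forward  = max(v, 0) + e
    backward = max(-v, 0) + e

and the reversibility ratio is r = e / |v|: the cyclic conversion between
the two pools relative to the net conversion.  The bounded transform
u = r / (1 + r) in [0, 1) is used by the optimiser.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["FluxState", "ratio_to_u", "u_to_ratio", "U_CAP"]

#: cap on the exchange transform u = r/(1+r); u = U_CAP corresponds to
#: r ~ 1e4, beyond which the labelling system is numerically fully mixed.
U_CAP = 0.9999


def ratio_to_u(r: float) -> float:
    if r < 0:
        raise ValueError("reversibility ratio must be >= 0")
    return r / (1.0 + r)


def u_to_ratio(u: float) -> float:
    if not 0.0 <= u <= U_CAP:
        raise ValueError(f"exchange transform u must lie in [0, {U_CAP}]")
    return u / (1.0 - u)


@dataclass
class FluxState:
    """Net flux per reaction plus exchange flux per reversible reaction.

    Fluxes are in the caller's units (the bundled presets use
    µM/h/µg protein); only ratios of fluxes matter to the steady-state
    labelling solve, units enter through the time integration.
    """

    net: dict[str, float]
    exchange: dict[str, float] = field(default_factory=dict)

    def __post_init__(self):
        for rid, e in self.exchange.items():
            if e < 0:
                raise ValueError(f"exchange flux of {rid} must be >= 0, got {e}")

    def forward(self, rid: str) -> float:
        v = self.net[rid]
        return max(v, 0.0) + self.exchange.get(rid, 0.0)

    def backward(self, rid: str) -> float:
        v = self.net[rid]
        return max(-v, 0.0) + self.exchange.get(rid, 0.0)

    def reversibility_ratio(self, rid: str) -> float:
        v = abs(self.net[rid])
        e = self.exchange.get(rid, 0.0)
        return np.inf if v == 0 and e > 0 else (e / v if v else 0.0)

    def replace(self, net: dict[str, float] | None = None,
                exchange: dict[str, float] | None = None) -> "FluxState":
        new_net = dict(self.net)
        new_exc = dict(self.exchange)
        if net:
            new_net.update(net)
        if exchange:
            new_exc.update(exchange)
        return FluxState(new_net, new_exc)

    def check_balance(self, model, tol: float = 1e-9) -> None:
        """Assert S·v_net = 0 over balanced metabolites."""
        from .network_model import stoichiometric_matrix

        S, rows = stoichiometric_matrix(model)
        v = np.array([self.net[r.id] for r in model.reactions])
        resid = S @ v
        worst = int(np.argmax(np.abs(resid))) if len(resid) else 0
        if len(resid) and abs(resid[worst]) > tol:
            raise ValueError(
                f"flux state violates steady state at {rows[worst]}: "
                f"imbalance {resid[worst]:.3g}"
            )
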
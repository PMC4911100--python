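"""ODE model structures for the neurovascular coupling behind the BOLD response.

Seven model structures implement three mechanistic hypotheses:

* **Metabolic feedback** (``Mm1``, ``Mm2``, ``Mm3``): neuronal activity raises
  glucose (and, partly, oxygen) consumption in the studied vessel volume; the
  resulting glucose deficit feeds back onto the blood flow, which restores
  supply.  The measured signal follows the oxy-/deoxyhemoglobin ratio.
  ``Mm1`` lets the *oxygen* deficit drive the flow; ``Mm2`` uses the glucose
  deficit with a delay chain between the input and metabolism; ``Mm3`` moves
  the delay chain between the glucose deficit and the flow, standing in for
  smooth-muscle action.

* **Neurotransmitter feed-forward** (``Mn1``, ``Mn2``): glutamate release opens
  calcium channels in neurons and astrocytes; neuronal calcium drives the
  NO -> cGMP vasodilating pathway, astrocytic calcium drives arachidonic-acid
  metabolites — EET and prostaglandins dilate, 20-HETE constricts.  There is
  no metabolism, so the blood flow deviation is a direct proxy for the output.
  ``Mn2`` is the minimized structure: a single dilating and a single
  constricting arm of three delay states each.

* **Extended feed-forward** (``Mnm1``, ``Mnm2``): the feed-forward flow module
  combined with the metabolic module.  Metabolism is driven directly by the
  input and there is no metabolic feedback on the flow; the output is the
  deviation of the oHb/dHb ratio.

Conventions
-----------
Non-regulated rates are mass action; each state equation is the sum of its in-
and out-going reactions.  The blood flow ``v`` is a *variable*, not a state:
it transports all four metabolic species in and out of the studied volume.
Basal concentrations are normalized to 1 au (signaling species are deviations
from basal, so their basal value is 0); inflow concentrations are chosen so
that the basal state is an exact steady state.  Parameter bounds default to
[1e-3, 1e3], explored on a log scale.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np

__all__ = [
    "ModelSpec",
    "ParameterSet",
    "BasalStateError",
    "make_model",
    "MODEL_NAMES",
    "ohb_rate",
    "REFERENCE_PARAMS",
]

MODEL_NAMES = ("Mm1", "Mm2", "Mm3", "Mn1", "Mn2", "Mnm1", "Mnm2")

#: Default parameter bounds (explored on a log10 scale during fitting).
DEFAULT_BOUNDS = (1e-3, 1e3)

#: The measurement scale maps dimensionless ratio/flow deviations (a few
#: percent at most) onto data in tens of au, so it gets a wider upper bound.
Y_SCALE_BOUNDS = (1e-3, 1e5)

#: The flow is floored at this fraction of basal flow; it can never reverse.
FLOW_FLOOR_FRAC = 1e-6

#: Length of every first-order delay chain.
CHAIN_LEN = 3


class BasalStateError(ValueError):
    """Raised when a parameter set admits no basal steady state."""


@dataclass
class ParameterSet:
    """One candidate parameter vector with provenance."""

    model: str
    names: tuple[str, ...]
    values: np.ndarray
    cost: float | None = None
    seed: int | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if len(self.values) != len(self.names):
            raise ValueError("values and names length mismatch")

    def as_dict(self) -> dict[str, float]:
        return dict(zip(self.names, map(float, self.values)))

    def __getitem__(self, name: str) -> float:
        return float(self.values[self.names.index(name)])


def ohb_rate(dHb: float, O2: float, oHb: float, k1f: float, k1b: float,
             v_flow: float, oHb_in: float) -> float:
    """Oxyhemoglobin balance in the studied vessel volume.

    d[oHb]/dt = k1f [dHb][O2] - k1b [oHb] + v_flow [oHb]_in - v_flow [oHb],
    i.e. hemoglobin–oxygen binding plus flow-mediated exchange with the
    incoming blood at concentration ``oHb_in``.
    """
    return k1f * dHb * O2 - k1b * oHb + v_flow * oHb_in - v_flow * oHb


@dataclass(frozen=True)
class ModelSpec:
    """A named ODE model structure: states, parameters, RHS, output map."""

    name: str
    family: str  # "metabolic" | "neuro" | "extended"
    state_names: tuple[str, ...]
    param_names: tuple[str, ...]
    _rhs: Callable = field(repr=False)
    _flow: Callable = field(repr=False)
    _output: Callable = field(repr=False)
    _x0: Callable = field(repr=False)
    equations_text: str = field(repr=False, default="")
    bounds: dict = field(default_factory=dict)

    @property
    def n_states(self) -> int:
        return len(self.state_names)

    @property
    def n_params(self) -> int:
        return len(self.param_names)

    @property
    def has_glucose(self) -> bool:
        return "G" in self.state_names

    @property
    def has_flow(self) -> bool:
        return True

    def param_bounds(self) -> list[tuple[float, float]]:
        return [self.bounds.get(n, DEFAULT_BOUNDS) for n in self.param_names]

    def make_params(self, mapping: dict[str, float] | None = None,
                    **kwargs: float) -> ParameterSet:
        """Build a ParameterSet from keyword values (all names required)."""
        d = dict(mapping or {})
        d.update(kwargs)
        missing = [n for n in self.param_names if n not in d]
        if missing:
            raise ValueError(f"{self.name}: missing parameters {missing}")
        extra = [n for n in d if n not in self.param_names]
        if extra:
            raise ValueError(f"{self.name}: unknown parameters {extra}")
        return ParameterSet(self.name, self.param_names,
                            np.array([d[n] for n in self.param_names]))

    def _pvec(self, p) -> np.ndarray:
        if isinstance(p, ParameterSet):
            return p.values
        return np.asarray(p, dtype=float)

    def rhs(self, x, p, u: float) -> np.ndarray:
        """Validated state-derivative evaluation f(x, p, u)."""
        x = np.asarray(x, dtype=float)
        pv = self._pvec(p)
        if not np.all(np.isfinite(x)):
            raise ValueError(f"{self.name}: non-finite state in rhs evaluation")
        if np.any(pv < 0):
            bad = self.param_names[int(np.argmax(pv < 0))]
            raise ValueError(f"{self.name}: negative parameter {bad}")
        return self._rhs(x, pv, u)

    def flow_variable(self, x, p) -> float:
        """The blood-flow variable v(x, p) (au/s)."""
        return float(self._flow(np.asarray(x, dtype=float), self._pvec(p)))

    def output(self, x, p) -> float:
        """Measurement map g: the simulated BOLD signal (au)."""
        return float(self._output(np.asarray(x, dtype=float), self._pvec(p)))

    def basal_steady_state(self, p) -> np.ndarray:
        """Basal state x0 with f(x0, p, 0) = 0 verified to 1e-9 (sup norm)."""
        pv = self._pvec(p)
        x0 = self._x0(pv)
        resid = self._rhs(x0, pv, 0.0)
        worst = int(np.argmax(np.abs(resid)))
        if not np.all(np.isfinite(resid)) or abs(resid[worst]) >= 1e-9:
            raise BasalStateError(
                f"{self.name}: basal residual {resid[worst]:.3g} on state "
                f"{self.state_names[worst]!r}"
            )
        return x0


# ---------------------------------------------------------------------------
# Metabolic module helpers
# ---------------------------------------------------------------------------

_MET_STATES = ("G", "O2", "oHb", "dHb")


def _met_inflows(v0, k1f, k1b, k_bas, n_b):
    """Inflow concentrations that balance basal consumption exactly.

    At basal (all species 1, flow v0, no stimulation) each transport term must
    offset the basal reaction flux, which fixes the inflow concentrations.
    """
    if v0 <= 0:
        raise BasalStateError("flow v0 must be > 0 to balance basal consumption")
    G_in = 1.0 + k_bas / v0
    O2_in = 1.0 + (n_b * k_bas + k1f - k1b) / v0
    oHb_in = 1.0 + (k1b - k1f) / v0
    dHb_in = 1.0 + (k1f - k1b) / v0
    return G_in, O2_in, oHb_in, dHb_in


def _met_rates(x, off, v, u_met, p_met):
    """Derivatives of (G, O2, oHb, dHb) at offset ``off`` in the state vector.

    ``u_met`` is the stimulated metabolic drive (dimensionless); consumption is
    mass action in the consumed species: glucose is metabolized at rate
    ``(k_bas + k_stim*u_met) * G`` and free oxygen at
    ``(n_b*k_bas + n_s*k_stim*u_met) * O2`` — the two stoichiometries encode
    how aerobic basal vs stimulated metabolism is, and first-order consumption
    keeps concentrations non-negative.
    """
    k1f, k1b, k_bas, k_stim, n_b, n_s, v0 = p_met
    G, O2, oHb, dHb = x[off], x[off + 1], x[off + 2], x[off + 3]
    G_in, O2_in, oHb_in, dHb_in = _met_inflows(v0, k1f, k1b, k_bas, n_b)
    stim = k_stim * u_met
    bind = k1f * dHb * O2 - k1b * oHb
    dG = v * (G_in - G) - (k_bas + stim) * G
    dO2 = -bind + v * (O2_in - O2) - (n_b * k_bas + n_s * stim) * O2
    doHb = bind + v * (oHb_in - oHb)
    ddHb = -bind + v * (dHb_in - dHb)
    return dG, dO2, doHb, ddHb


def _ratio_output(x, off, y_scale):
    oHb, dHb = x[off + 2], x[off + 3]
    if dHb <= 0:
        raise ValueError("dHb <= 0: oHb/dHb output undefined")
    return y_scale * (oHb / dHb - 1.0)


# ---------------------------------------------------------------------------
# Metabolic feedback structures Mm1 / Mm2 / Mm3
# ---------------------------------------------------------------------------

_MM_PARAMS = ("v0", "y_scale", "k1f", "k1b", "k_bas", "k_stim",
              "n_b", "n_s", "k_f", "k_d")

_MM_EQUATIONS = """\
states: G, O2, oHb, dHb, D1..D3 (delay chain)
flow:   Mm1: v = v0*(1 + k_f*max(0, 1 - O2))
        Mm2: v = v0*(1 + k_f*max(0, 1 - G))
        Mm3: v = v0*(1 + k_f*D3)
drive:  Mm1/Mm2: m = D3 (chain driven by u);  Mm3: m = u (direct)
chain:  Mm1/Mm2: dD1/dt = k_d*(u - D1)
        Mm3:     dD1/dt = k_d*(max(0, 1 - G) - D1)
        dDi/dt = k_d*(D[i-1] - Di)
dG/dt   = v*(G_in - G) - (k_bas + k_stim*m)
dO2/dt  = k1b*oHb - k1f*dHb*O2 + v*(O2_in - O2) - (n_b*k_bas + n_s*k_stim*m)
doHb/dt = k1f*dHb*O2 - k1b*oHb + v*(oHb_in - oHb)
ddHb/dt = k1b*oHb - k1f*dHb*O2 + v*(dHb_in - dHb)
output: y = y_scale*(oHb/dHb - 1)
inflows (steady-state balance): G_in = 1 + k_bas/v0;
  O2_in = 1 + (n_b*k_bas + k1f - k1b)/v0; oHb_in = 1 + (k1b - k1f)/v0;
  dHb_in = 1 + (k1f - k1b)/v0
"""


def _build_metabolic(name: str) -> ModelSpec:
    states = _MET_STATES + ("D1", "D2", "D3")
    iv0, iy, ik1f, ik1b, ikbas, ikstim, inb, ins, ikf, ikd = range(10)

    def flow(x, p):
        if name == "Mm1":
            deficit = max(0.0, 1.0 - x[1])  # O2 deficit
            return p[iv0] * (1.0 + p[ikf] * deficit)
        if name == "Mm2":
            deficit = max(0.0, 1.0 - x[0])  # glucose deficit
            return p[iv0] * (1.0 + p[ikf] * deficit)
        return p[iv0] * (1.0 + p[ikf] * x[6])  # Mm3: delayed deficit D3

    def rhs(x, p, u):
        v = flow(x, p)
        kd = p[ikd]
        if name == "Mm3":
            u_met = u
            src = max(0.0, 1.0 - x[0])
        else:
            u_met = x[6]  # D3
            src = u
        p_met = (p[ik1f], p[ik1b], p[ikbas], p[ikstim], p[inb], p[ins], p[iv0])
        dG, dO2, doHb, ddHb = _met_rates(x, 0, v, u_met, p_met)
        dD1 = kd * (src - x[4])
        dD2 = kd * (x[4] - x[5])
        dD3 = kd * (x[5] - x[6])
        return np.array([dG, dO2, doHb, ddHb, dD1, dD2, dD3])

    def output(x, p):
        return _ratio_output(x, 0, p[iy])

    def x0(p):
        if p[iv0] <= 0:
            raise BasalStateError("flow v0 must be > 0 to balance basal consumption")
        return np.array([1.0, 1.0, 1.0, 1.0, 0.0, 0.0, 0.0])

    return ModelSpec(name=name, family="metabolic", state_names=states,
                     param_names=_MM_PARAMS, _rhs=rhs, _flow=flow,
                     _output=output, _x0=x0, equations_text=_MM_EQUATIONS,
                     bounds={"y_scale": Y_SCALE_BOUNDS})


# ---------------------------------------------------------------------------
# Neurotransmitter feed-forward structures Mn1 / Mn2
# ---------------------------------------------------------------------------

_MN1_SIGNALING = ("Glu", "Ca_n", "Ca_a", "NO", "cGMP", "AA", "EET", "PG", "HETE")
_MN1_CHAINS = ("cGMP", "EET", "PG", "HETE")  # each feeds the flow via 3 delays
_MN1_STATES = _MN1_SIGNALING + tuple(
    f"S{i}{sp}" for sp in _MN1_CHAINS for i in range(1, CHAIN_LEN + 1)
)
_MN1_PARAMS = (
    "k_g", "k_gc",          # glutamate release / clearance
    "k_c1", "k_c2",         # neuronal calcium in / out
    "k_c3", "k_c4",         # astrocytic calcium in / out
    "k_n1", "k_n2",         # NO production / degradation
    "k_m1", "k_m2",         # cGMP production / degradation
    "k_a1", "k_a2",         # AA production (Ca_a * PL) / degradation
    "k_e1", "k_e2",         # EET production / degradation
    "k_p1", "k_p2",         # PG production / degradation
    "k_h1", "k_h2",         # 20-HETE production / degradation
    "PL",                   # phospholipase A2 abundance
    "kd_cGMP", "kd_EET", "kd_PG", "kd_HETE",  # delay-chain rates
    "w_cGMP", "w_EET", "w_PG", "w_HETE",      # flow weights (HETE constricts)
    "v0", "y_scale",
)

_MN1_EQUATIONS = """\
signaling (deviations from basal, basal = 0):
dGlu/dt  = k_g*u - k_gc*Glu
dCa_n/dt = k_c1*Glu - k_c2*Ca_n        dCa_a/dt = k_c3*Glu - k_c4*Ca_a
dNO/dt   = k_n1*Ca_n - k_n2*NO         dcGMP/dt = k_m1*NO - k_m2*cGMP
dAA/dt   = k_a1*Ca_a*PL - k_a2*AA
dEET/dt  = k_e1*AA - k_e2*EET          dPG/dt   = k_p1*AA - k_p2*PG
dHETE/dt = k_h1*AA - k_h2*HETE
chains: for sp in {cGMP, EET, PG, HETE}: dS1sp/dt = kd_sp*(sp - S1sp);
        dSisp/dt = kd_sp*(S[i-1]sp - Sisp), i = 2..3
flow:   v = max(v0 + w_cGMP*S3cGMP + w_EET*S3EET + w_PG*S3PG - w_HETE*S3HETE,
                1e-6*v0)
output: y = y_scale*(v - v0)
"""


def _build_mn1() -> ModelSpec:
    n_sig = len(_MN1_SIGNALING)
    chain_off = {sp: n_sig + i * CHAIN_LEN for i, sp in enumerate(_MN1_CHAINS)}
    pidx = {n: i for i, n in enumerate(_MN1_PARAMS)}
    sidx = {n: i for i, n in enumerate(_MN1_STATES)}
    iv0, iy = pidx["v0"], pidx["y_scale"]
    last = {sp: chain_off[sp] + CHAIN_LEN - 1 for sp in _MN1_CHAINS}

    def flow(x, p):
        v = (p[iv0]
             + p[pidx["w_cGMP"]] * x[last["cGMP"]]
             + p[pidx["w_EET"]] * x[last["EET"]]
             + p[pidx["w_PG"]] * x[last["PG"]]
             - p[pidx["w_HETE"]] * x[last["HETE"]])
        return max(v, FLOW_FLOOR_FRAC * p[iv0])

    def rhs(x, p, u):
        dx = np.empty(len(_MN1_STATES))
        Glu, Can, Caa = x[0], x[1], x[2]
        NO, cGMP, AA = x[3], x[4], x[5]
        EET, PG, HETE = x[6], x[7], x[8]
        dx[0] = p[pidx["k_g"]] * u - p[pidx["k_gc"]] * Glu
        dx[1] = p[pidx["k_c1"]] * Glu - p[pidx["k_c2"]] * Can
        dx[2] = p[pidx["k_c3"]] * Glu - p[pidx["k_c4"]] * Caa
        dx[3] = p[pidx["k_n1"]] * Can - p[pidx["k_n2"]] * NO
        dx[4] = p[pidx["k_m1"]] * NO - p[pidx["k_m2"]] * cGMP
        dx[5] = p[pidx["k_a1"]] * Caa * p[pidx["PL"]] - p[pidx["k_a2"]] * AA
        dx[6] = p[pidx["k_e1"]] * AA - p[pidx["k_e2"]] * EET
        dx[7] = p[pidx["k_p1"]] * AA - p[pidx["k_p2"]] * PG
        dx[8] = p[pidx["k_h1"]] * AA - p[pidx["k_h2"]] * HETE
        for sp in _MN1_CHAINS:
            kd = p[pidx["kd_" + sp]]
            off = chain_off[sp]
            src = x[sidx[sp]]
            dx[off] = kd * (src - x[off])
            for i in range(1, CHAIN_LEN):
                dx[off + i] = kd * (x[off + i - 1] - x[off + i])
        return dx

    def output(x, p):
        return p[iy] * (flow(x, p) - p[iv0])

    def x0(p):
        return np.zeros(len(_MN1_STATES))

    return ModelSpec(name="Mn1", family="neuro", state_names=_MN1_STATES,
                     param_names=_MN1_PARAMS, _rhs=rhs, _flow=flow,
                     _output=output, _x0=x0, equations_text=_MN1_EQUATIONS,
                     bounds={"y_scale": Y_SCALE_BOUNDS})


_MN2_STATES = ("S1d", "S2d", "S3d", "S1c", "S2c", "S3c")
_MN2_PARAMS = ("a1", "a2", "a3", "a4", "a5", "a6",
               "b1", "b2", "b3", "b4", "b5", "b6",
               "w_d", "w_c", "v0", "y_scale")

_MN2_EQUATIONS = """\
dilating arm:     dS1d/dt = a1*u - a2*S1d; dS2d/dt = a3*S1d - a4*S2d;
                  dS3d/dt = a5*S2d - a6*S3d
constricting arm: dS1c/dt = b1*u - b2*S1c; dS2c/dt = b3*S1c - b4*S2c;
                  dS3c/dt = b5*S2c - b6*S3c
flow:   v = max(v0 + w_d*S3d - w_c*S3c, 1e-6*v0)
output: y = y_scale*(v - v0)
"""


def _build_mn2() -> ModelSpec:
    def flow(x, p):
        v = p[14] + p[12] * x[2] - p[13] * x[5]
        return max(v, FLOW_FLOOR_FRAC * p[14])

    def rhs(x, p, u):
        return np.array([
            p[0] * u - p[1] * x[0],
            p[2] * x[0] - p[3] * x[1],
            p[4] * x[1] - p[5] * x[2],
            p[6] * u - p[7] * x[3],
            p[8] * x[3] - p[9] * x[4],
            p[10] * x[4] - p[11] * x[5],
        ])

    def output(x, p):
        return p[15] * (flow(x, p) - p[14])

    def x0(p):
        return np.zeros(6)

    return ModelSpec(name="Mn2", family="neuro", state_names=_MN2_STATES,
                     param_names=_MN2_PARAMS, _rhs=rhs, _flow=flow,
                     _output=output, _x0=x0, equations_text=_MN2_EQUATIONS,
                     bounds={"y_scale": Y_SCALE_BOUNDS})


# ---------------------------------------------------------------------------
# Extended structures Mnm1 / Mnm2: feed-forward flow + metabolism
# ---------------------------------------------------------------------------

_MET_EXT_PARAMS = ("k1f", "k1b", "k_bas", "k_stim", "n_b", "n_s")

_MNM_NOTE = """\
metabolic module (states G, O2, oHb, dHb appended after the flow module):
  metabolism is driven directly by the input (m = u); the flow v comes from
  the feed-forward module — there is no metabolic feedback on the flow.
  Equations as in the metabolic family with v from the flow module.
output: y = y_scale*(oHb/dHb - 1)
"""


def _build_extended(name: str) -> ModelSpec:
    base = _build_mn1() if name == "Mnm1" else _build_mn2()
    states = base.state_names + _MET_STATES
    params = base.param_names + _MET_EXT_PARAMS
    n_base_states = base.n_states
    n_base_params = base.n_params
    pidx = {n: i for i, n in enumerate(params)}
    iv0 = base.param_names.index("v0")
    iy = base.param_names.index("y_scale")
    imet = tuple(pidx[n] for n in _MET_EXT_PARAMS)
    base_rhs, base_flow = base._rhs, base._flow

    def flow(x, p):
        return base_flow(x, p)

    def rhs(x, p, u):
        dx_base = base_rhs(x, p, u)
        v = base_flow(x, p)
        k1f, k1b, k_bas, k_stim, n_b, n_s = (p[i] for i in imet)
        p_met = (k1f, k1b, k_bas, k_stim, n_b, n_s, p[iv0])
        d_met = _met_rates(x, n_base_states, v, u, p_met)
        return np.concatenate([dx_base, d_met])

    def output(x, p):
        return _ratio_output(x, n_base_states, p[iy])

    def x0(p):
        if p[iv0] <= 0:
            raise BasalStateError("flow v0 must be > 0 to balance basal consumption")
        return np.concatenate([np.zeros(n_base_states), np.ones(4)])

    return ModelSpec(
        name=name, family="extended", state_names=states, param_names=params,
        _rhs=rhs, _flow=flow, _output=output, _x0=x0,
        equations_text=base.equations_text + _MNM_NOTE,
        bounds={"y_scale": Y_SCALE_BOUNDS},
    )


_BUILDERS = {
    "Mm1": lambda: _build_metabolic("Mm1"),
    "Mm2": lambda: _build_metabolic("Mm2"),
    "Mm3": lambda: _build_metabolic("Mm3"),
    "Mn1": _build_mn1,
    "Mn2": _build_mn2,
    "Mnm1": lambda: _build_extended("Mnm1"),
    "Mnm2": lambda: _build_extended("Mnm2"),
}


def make_model(name: str) -> ModelSpec:
    """Return the fully wired model structure for ``name``.

    Valid names: Mm1, Mm2, Mm3 (metabolic feedback), Mn1, Mn2 (neurotransmitter
    feed-forward), Mnm1, Mnm2 (extended feed-forward with metabolism).
    """
    if name not in _BUILDERS:
        raise ValueError(f"unknown model structure {name!r}; choose from {MODEL_NAMES}")
    return _BUILDERS[name]()


# ---------------------------------------------------------------------------
# Reference parameter sets
# ---------------------------------------------------------------------------

#: Documented parameter sets used in tests, demos and regime studies (see
#: docs/methods.md for how they were chosen).  The three Mm2 sets differ only
#: in the stimulated oxygen stoichiometry n_s: fully aerobic (n_s = n_b)
#: yields an initial dip but no peak; fully anaerobic (n_s = 0) a peak but no
#: dip; partly anaerobic (0 < n_s < n_b) both.  The Mn2 set realizes the
#: constriction/dilation balance (early, lower, slowly decaying constrictor)
#: whose dip is vasoconstrictive; the Mnm2 set produces all three features
#: with a metabolic dip while the flow stays within 2 % of basal.  The Mm3
#: set exhibits the near-depletion of glucose that makes that structure
#: biologically implausible.
_MM2_BASE = dict(v0=0.5, y_scale=1000.0, k1f=0.3, k1b=0.3, k_bas=0.2,
                 k_stim=2.0, n_b=1.0, n_s=0.5, k_f=5.0, k_d=1.0)

REFERENCE_PARAMS: dict[str, dict[str, float]] = {
    "Mm2_aerobic": dict(_MM2_BASE, n_s=1.0),
    "Mm2_anaerobic": dict(_MM2_BASE, n_s=0.0),
    "Mm2_mixed": dict(_MM2_BASE, n_s=0.5),
    "Mm3_depleting": dict(v0=0.3, y_scale=1000.0, k1f=0.3, k1b=0.3,
                          k_bas=0.2, k_stim=15.0, n_b=1.0, n_s=0.3,
                          k_f=60.0, k_d=0.8),
    "Mn2_canonical": dict(a1=2.0, a2=0.5, a3=0.5, a4=0.55, a5=0.5, a6=0.7,
                          b1=4.0, b2=4.0, b3=4.0, b4=4.0, b5=0.4, b6=0.08,
                          w_d=7.0, w_c=2.2, v0=0.4, y_scale=22.0),
    "Mnm2_reference": dict(a1=2.0, a2=0.3, a3=0.35, a4=0.45, a5=0.4, a6=0.6,
                           b1=1.0, b2=0.8, b3=0.5, b4=0.5, b5=0.4, b6=0.07,
                           w_d=2.0, w_c=1.0, v0=0.4, y_scale=300.0,
                           k1f=3.0, k1b=3.0, k_bas=0.2, k_stim=0.4,
                           n_b=1.0, n_s=0.6),
}


def reference_parameter_set(key: str) -> ParameterSet:
    """Look up a documented reference parameter set by key, e.g. 'Mm2_mixed'."""
    if key not in REFERENCE_PARAMS:
        raise KeyError(f"no reference parameter set {key!r}; "
                       f"available: {sorted(REFERENCE_PARAMS)}")
    model = make_model(key.split("_")[0])
    return model.make_params(REFERENCE_PARAMS[key])
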
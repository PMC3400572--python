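"""Time-invariant two-compartment NMDA circuit.

Two nodes -- a proximal compartment doubling as the soma readout and a
distal dendritic compartment -- are joined by an axial conductance; each
node carries a leak to rest and a steady NMDA conductance proportional to
its synapse count, gated by a softened magnesium block
``B(V) = 1/(1 + exp(-(V + 22)/12))`` (the softening stands in for the
voltage-independent AMPA fraction that the circuit omits). Kirchhoff's
current law at the two nodes:

    g_leak_dist (V_d - E_rest) + g_axial (V_d - V_p)
        = N_dist g_nmda B(V_d) (E_syn - V_d)
    g_leak_prox (V_p - E_rest) + g_axial (V_p - V_d)
        = N_prox g_nmda B(V_p) (E_syn - V_p)

The distal equation is explicit in ``V_p``, so it eliminates the proximal
voltage; the resulting one-dimensional residual in ``V_d`` is scanned over
[E_rest, E_syn] for sign changes and each bracketed root is refined. The
root continuously connected to rest (the lowest ``V_d``) is the default
solution; all roots are retained for bistability analysis. Conductances
and currents are in arbitrary units (A.U.); voltages are absolute mV so
that the printed Mg-block midpoint is meaningful, with a final linear
``output_scale`` absorbing units into a somatic response in mV.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

import numpy as np
from scipy.optimize import brentq

__all__ = [
    "TwoCompParams",
    "SteadyState",
    "SolverError",
    "solve_steady_state",
    "response_surface",
    "fit_output_scale",
    "compute_cto",
]


class SolverError(RuntimeError):
    pass


@dataclass(frozen=True)
class TwoCompParams:
    """Hand-tunable circuit parameters (conductances in A.U.)."""

    g_axial: float = 2.5
    g_leak_prox: float = 4.0
    g_leak_dist: float = 0.25
    g_nmda_unit: float = 0.5
    mg_half: float = 22.0
    mg_slope: float = 12.0
    e_rest: float = -70.0
    e_syn: float = 0.0
    output_scale: float = 1.0

    def __post_init__(self):
        if min(self.g_axial, self.g_leak_prox, self.g_leak_dist,
               self.g_nmda_unit) < 0:
            raise ValueError("conductances must be >= 0")
        if self.mg_slope <= 0:
            raise ValueError("mg_slope must be > 0")

    def b(self, v):
        arg = np.clip(-(np.asarray(v, dtype=float) + self.mg_half)
                      / self.mg_slope, -60.0, 60.0)
        out = 1.0 / (1.0 + np.exp(arg))
        return float(out) if out.ndim == 0 else out


@dataclass(frozen=True)
class SteadyState:
    v_prox: float
    v_dist: float
    branch: Literal["rest-connected", "upper", "other"]
    all_roots: tuple[tuple[float, float], ...]  # (v_prox, v_dist) per root


def _v_prox_from_v_dist(p: TwoCompParams, v_d, n_dist):
    """Explicit elimination of the proximal voltage via the distal KCL."""
    i_nmda = n_dist * p.g_nmda_unit * p.b(v_d) * (p.e_syn - v_d)
    return v_d - (i_nmda - p.g_leak_dist * (v_d - p.e_rest)) / p.g_axial


def _residual(p: TwoCompParams, v_d, n_prox, n_dist):
    v_p = _v_prox_from_v_dist(p, v_d, n_dist)
    return (p.g_leak_prox * (v_p - p.e_rest) + p.g_axial * (v_p - v_d)
            - n_prox * p.g_nmda_unit * p.b(v_p) * (p.e_syn - v_p))


def solve_steady_state(p: TwoCompParams, n_prox: float, n_dist: float,
                       n_scan: int = 4001) -> SteadyState:
    """All steady states of the circuit; the rest-connected one is primary.

    Scans the distal voltage over [E_rest - 1, E_syn + 1] for sign changes
    of the eliminated KCL residual and refines each bracket with Brent's
    method. Both raw KCL residuals of every returned root are below 1e-9.
    """
    if n_prox < 0 or n_dist < 0:
        raise ValueError("synapse counts must be >= 0")
    lo, hi = p.e_rest - 1.0, p.e_syn + 1.0
    grid = np.linspace(lo, hi, n_scan)
    res = _residual(p, grid, n_prox, n_dist)
    roots: list[float] = []
    sign = np.sign(res)
    for i in np.flatnonzero(sign[:-1] * sign[1:] < 0):
        roots.append(brentq(lambda v: _residual(p, v, n_prox, n_dist),
                            grid[i], grid[i + 1], xtol=1e-15, rtol=8.9e-16))
    for i in np.flatnonzero(res == 0):
        roots.append(float(grid[i]))
    roots = sorted(roots)
    roots = [r for k, r in enumerate(roots)
             if k == 0 or r - roots[k - 1] > 1e-8]
    if not roots:
        raise SolverError(
            f"no steady state found for N_prox={n_prox}, N_dist={n_dist}")
    pairs = tuple((float(_v_prox_from_v_dist(p, vd, n_dist)), float(vd))
                  for vd in roots)
    labels = ["rest-connected"] + ["other"] * max(0, len(pairs) - 2)
    if len(pairs) > 1:
        labels.append("upper")
    return SteadyState(v_prox=pairs[0][0], v_dist=pairs[0][1],
                       branch="rest-connected", all_roots=pairs)


def response_surface(p: TwoCompParams,
                     n_prox=None, n_dist=None) -> np.ndarray:
    """Scaled somatic response grid; entry [i, j] is for (n_prox[i], n_dist[j]).

    The response is ``output_scale * (V_prox - E_rest)`` on the
    rest-connected branch.
    """
    n_prox = np.arange(41) if n_prox is None else np.asarray(n_prox)
    n_dist = np.arange(41) if n_dist is None else np.asarray(n_dist)
    out = np.empty((len(n_prox), len(n_dist)))
    for i, np_i in enumerate(n_prox):
        for j, nd_j in enumerate(n_dist):
            ss = solve_steady_state(p, float(np_i), float(nd_j))
            out[i, j] = p.output_scale * (ss.v_prox - p.e_rest)
    return out


def fit_output_scale(surface: np.ndarray, target_peak: float) -> float:
    """Linear factor making the surface's overall peak equal ``target_peak``."""
    peak = float(np.max(surface))
    if peak <= 0:
        raise ValueError("surface has no positive response to scale")
    return target_peak / peak


def compute_cto(p: TwoCompParams, v: float, n_drive: float,
                node: Literal["prox", "dist"], n_other: float = 0.0) -> float:
    """Current-to-overcome at a node held at voltage ``v`` (A.U. current).

    Defined as the NMDA drive minus the net passive (leak + axial) current
    leaving the node, with the other node settled at its own rest-connected
    steady voltage given ``v``; zero exactly at a steady-state solution.
    """
    if node not in ("prox", "dist"):
        raise ValueError("node must be 'prox' or 'dist'")
    g_leak_here = p.g_leak_dist if node == "dist" else p.g_leak_prox
    g_leak_there = p.g_leak_prox if node == "dist" else p.g_leak_dist
    # settle the other node given v at this node
    def other_residual(u):
        return (g_leak_there * (u - p.e_rest) + p.g_axial * (u - v)
                - n_other * p.g_nmda_unit * p.b(u) * (p.e_syn - u))
    grid = np.linspace(p.e_rest - 1.0, p.e_syn + 1.0, 2001)
    res = other_residual(grid)
    exact = np.flatnonzero(res == 0)
    sign = np.sign(res)
    brackets = np.flatnonzero(sign[:-1] * sign[1:] < 0)
    if len(exact) and (len(brackets) == 0 or exact[0] < brackets[0]):
        u = float(grid[exact[0]])  # root sits exactly on a grid point
    elif len(brackets):
        i = brackets[0]  # rest-connected root: lowest
        u = brentq(other_residual, grid[i], grid[i + 1], xtol=1e-12)
    else:
        raise SolverError("no settled voltage for the passive node")
    i_passive = g_leak_here * (v - p.e_rest) + p.g_axial * (v - u)
    i_drive = n_drive * p.g_nmda_unit * p.b(v) * (p.e_syn - v)
    return float(i_drive - i_passive)
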
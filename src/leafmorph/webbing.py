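"""Webbing: geometric fairing of the leaf margin.

The margin between vein tips resists stretching and bending.  This is
modelled as explicit gradient descent on a discrete fairing energy

    E = sum_edges  w_e (|e| - r_e)^2  +  sum_points  w_p |p[i-1] - 2 p[i] + p[i+1]|^2

where r_e is a rest length (current length times ``1 - relaxation``; the
default relaxation of 1 gives the classic membrane energy whose minimum is
the straight chord between pinned points).  Convergence points and the two
petiole-base endpoints are pinned: protrusion tips are moved only by
growth, never smoothed away.

Morphogens modulate the webbing locally: each point's weights are
multiplied by the product of the ``webbing_factor`` of the morphogens
active there (a sinus morphogen with factor < 1 deepens sinuses).  A
proximal/distal stretch asymmetry around each convergence point skews
teeth into serrations pointing toward the leaf apex.

The descent step is stability-bounded and sub-stepped (halved) whenever it
would increase the energy or self-intersect the margin, so the energy is
nonincreasing across iterations.
"""

from __future__ import annotations

import numpy as np

from .core_model import Margin, MorphogenRule, WebbingParams

__all__ = ["fair_margin", "fairing_energy", "fairing_weights"]


def _point_webbing_factors(
    margin: Margin, rules: dict[str, MorphogenRule] | None
) -> np.ndarray:
    out = np.ones(len(margin.points))
    if rules:
        for i, p in enumerate(margin.points):
            f = 1.0
            for name, s in p.morphogens.items():
                rule = rules.get(name)
                if rule is not None and s > 0:
                    f *= 1.0 + s * (rule.webbing_factor - 1.0)
            out[i] = f
    return out


def fairing_weights(
    margin: Margin,
    webbing: WebbingParams,
    rules: dict[str, MorphogenRule] | None = None,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Effective (edge stretch weights, point bend weights, rest lengths).

    The stretch weight of an edge on the proximal side of its nearest
    convergence point (closer to the leaf base than the CP, in the
    Euclidean sense) is multiplied by ``webbing.asym``.
    """
    pos = margin.positions()
    n = len(pos)
    factors = _point_webbing_factors(margin, rules)
    edge_f = 0.5 * (factors[:-1] + factors[1:])
    edge_w = webbing.stretch * edge_f
    point_w = webbing.bend * factors

    if webbing.asym != 1.0:
        cps = margin.cp_indices()
        if cps:
            base = 0.5 * (pos[0] + pos[-1])
            cp_pos = pos[cps]
            mids = 0.5 * (pos[:-1] + pos[1:])
            # nearest CP by straight-line distance; proximal = closer to base
            d = np.linalg.norm(mids[:, None, :] - cp_pos[None, :, :], axis=2)
            nearest = np.argmin(d, axis=1)
            cp_base = np.linalg.norm(cp_pos - base, axis=1)
            mid_base = np.linalg.norm(mids - base, axis=1)
            proximal = mid_base < cp_base[nearest]
            edge_w = np.where(proximal, edge_w * webbing.asym, edge_w)

    lengths = np.linalg.norm(np.diff(pos, axis=0), axis=1)
    rest = lengths * (1.0 - webbing.relaxation)
    return edge_w, point_w, rest


def fairing_energy(
    pos: np.ndarray, edge_w: np.ndarray, rest: np.ndarray, point_w: np.ndarray
) -> float:
    """Discrete fairing energy of a polyline."""
    e = np.diff(pos, axis=0)
    lengths = np.linalg.norm(e, axis=1)
    stretch = float(np.sum(edge_w * (lengths - rest) ** 2))
    if len(pos) >= 3:
        d2 = pos[:-2] - 2 * pos[1:-1] + pos[2:]
        bend = float(np.sum(point_w[1:-1] * np.sum(d2**2, axis=1)))
    else:
        bend = 0.0
    return stretch + bend


def _gradient(
    pos: np.ndarray, edge_w: np.ndarray, rest: np.ndarray, point_w: np.ndarray
) -> np.ndarray:
    n = len(pos)
    grad = np.zeros_like(pos)
    e = np.diff(pos, axis=0)
    lengths = np.linalg.norm(e, axis=1)
    safe = np.where(lengths > 1e-30, lengths, 1.0)
    unit = e / safe[:, None]
    coef = 2.0 * edge_w * (lengths - rest)
    f = coef[:, None] * unit  # dE/d(end) for each edge
    grad[1:] += f
    grad[:-1] -= f
    if n >= 3:
        d2 = pos[:-2] - 2 * pos[1:-1] + pos[2:]
        g = 2.0 * point_w[1:-1, None] * d2
        grad[:-2] += g
        grad[1:-1] -= 2.0 * g
        grad[2:] += g
    return grad


def fair_margin(
    margin: Margin,
    webbing: WebbingParams,
    rules: dict[str, MorphogenRule] | None = None,
) -> Margin:
    """Run ``webbing.iterations`` fairing iterations on the margin.

    Convergence points and base endpoints stay fixed.  Each iteration is an
    explicit gradient-descent step with a stability-bounded step size,
    halved until the energy does not increase and the margin stays simple.
    """
    if webbing.iterations == 0 or (webbing.stretch == 0 and webbing.bend == 0):
        return margin.copy()

    out = margin.copy()
    edge_w, point_w, rest = fairing_weights(out, webbing, rules)
    pinned = np.zeros(len(out.points), dtype=bool)
    pinned[0] = pinned[-1] = True
    for i in out.cp_indices():
        pinned[i] = True

    pos = out.positions()
    # crude Lipschitz bound on the energy Hessian
    lip = 8.0 * float(edge_w.max(initial=0.0)) + 32.0 * float(point_w.max(initial=0.0))
    if lip == 0.0:
        return out
    base_step = 0.9 / lip
    energy = fairing_energy(pos, edge_w, rest, point_w)

    for _ in range(webbing.iterations):
        grad = _gradient(pos, edge_w, rest, point_w)
        grad[pinned] = 0.0
        step = base_step
        for _ in range(40):
            cand = pos - step * grad
            new_energy = fairing_energy(cand, edge_w, rest, point_w)
            if new_energy <= energy + 1e-15:
                out.set_positions(cand)
                if out.is_simple():
                    pos, energy = cand, new_energy
                    break
            step *= 0.5
        else:
            out.set_positions(pos)  # no admissible step: stop moving
            break
    out.set_positions(pos)
    return out
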
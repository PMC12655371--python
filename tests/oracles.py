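"""Independent oracles used to check the package's closed forms.

Kept deliberately naive and separate from the implementation: a direct
microspecies enumeration for speciation and a finite-difference diffusion
solver for series permeability stacks.
"""

from __future__ import annotations

import itertools

import numpy as np


def brute_force_uncharged_fraction(sites, pH: float) -> float:
    """Uncharged fraction by direct enumeration of all protonation states.

    ``sites`` is a list of (pKa, kind) pairs.  Each state's statistical
    weight is the product of site factors: a deprotonated site contributes
    10**(pH - pKa) relative to its protonated form.  The uncharged state has
    every acid protonated and every base deprotonated.
    """
    total = 0.0
    neutral = 0.0
    for states in itertools.product([True, False], repeat=len(sites)):
        w = 1.0
        uncharged = True
        for (pka, kind), protonated in zip(sites, states):
            if not protonated:
                w *= 10.0 ** (pH - pka)
            if kind == "acid" and not protonated:
                uncharged = False
            if kind == "base" and protonated:
                uncharged = False
        total += w
        if uncharged:
            neutral = w
    return neutral / total


def finite_difference_series_papp(permeabilities, n_per_layer: int = 400) -> float:
    """Steady-state permeability of a stack of purely diffusive slabs.

    Each barrier with permeability ``p`` is modelled as a unit-thickness
    slab with diffusivity ``D = p``; the donor face is held at concentration
    1 and the acceptor face at 0.  The discretised steady-state diffusion
    problem is solved and the flux through the acceptor face returned,
    which equals the apparent permeability for unit donor concentration.
    """
    # conductances between adjacent grid nodes
    conductances = []
    for p in permeabilities:
        dx = 1.0 / n_per_layer
        conductances.extend([p / dx] * n_per_layer)
    n_nodes = len(conductances) - 1  # interior nodes
    main = np.zeros(n_nodes)
    lower = np.zeros(n_nodes - 1)
    upper = np.zeros(n_nodes - 1)
    rhs = np.zeros(n_nodes)
    for i in range(n_nodes):
        g_left, g_right = conductances[i], conductances[i + 1]
        main[i] = g_left + g_right
        if i > 0:
            lower[i - 1] = -g_left
        else:
            rhs[i] = g_left * 1.0  # donor boundary
        if i < n_nodes - 1:
            upper[i] = -g_right
    A = np.diag(main) + np.diag(lower, -1) + np.diag(upper, 1)
    conc = np.linalg.solve(A, rhs)
    return conductances[-1] * conc[-1]
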
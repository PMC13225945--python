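"""Closed-form propagation of the infusion compartment ODEs.

The two-compartment system for central/peripheral concentrations (C_A, C_B)
under a constant infusion rate I is

    dC_A/dt = I/V1 - (CL/V1) C_A - (Q/V1)(C_A - C_B)
    dC_B/dt = (Q/V2)(C_A - C_B)

i.e. C' = A C + b with A = [[-(CL+Q)/V1, Q/V1], [Q/V2, -Q/V2]] and
b = (I/V1, 0).  For strictly positive parameters A has two distinct real
non-positive eigenvalues (the discriminant is (a11-a22)^2 + 4 a12 a21 > 0),
so the matrix functions used below are evaluated in Lagrange (spectral
interpolation) form:

    e^{A dt}          -> f(lam)   = e^{lam dt}
    int_0^dt e^{As}ds -> phi1(lam) = (e^{lam dt} - 1)/lam
    int_0^dt (dt-s) e^{As} ds -> phi2(lam) = (e^{lam dt} - 1 - lam dt)/lam^2

The same scalar expressions run on plain float64 arrays (the deterministic
PK core) and on autodiff Tensors (the differentiable PK layer of the
recurrent models), so both paths produce identical floating-point results.

These formulas assume lam1 != lam2 and lam != 0, which holds whenever
CL, Q, V1, V2 > 0.  Degenerate edges (Q = 0, repeated eigenvalues) are
handled by NumPy-only limiting forms in `pk_core`.
"""

from __future__ import annotations

from . import autodiff as ad


def eig_2c(v1, v2, q, cl):
    """Eigenvalues and matrix entries of the 2-compartment system."""
    a11 = -(cl + q) / v1
    a12 = q / v1
    a21 = q / v2
    a22 = -q / v2
    tr = a11 + a22
    # (a11-a22)^2 + 4 a12 a21 == tr^2 - 4 det, but cannot round negative
    d = a11 - a22
    disc = ad.sqrt(d * d + 4.0 * a12 * a21)
    lam1 = 0.5 * (tr + disc)
    lam2 = 0.5 * (tr - disc)
    return a11, a12, a21, a22, lam1, lam2, disc


def step_2c(ca, cb, v1, v2, q, cl, rate, dt, want_auc: bool = False):
    """Advance (C_A, C_B) by `dt` under constant infusion `rate` (mg/h).

    Returns (ca_end, cb_end) or (ca_end, cb_end, auc) where `auc` is the
    exact integral of C_A over the step.  All arguments may be scalars,
    arrays, or Tensors (broadcasting applies).
    """
    a11, a12, a21, a22, lam1, lam2, disc = eig_2c(v1, v2, q, cl)

    f1 = ad.exp(lam1 * dt)
    f2 = ad.exp(lam2 * dt)
    p1_1 = ad.expm1(lam1 * dt) / lam1
    p1_2 = ad.expm1(lam2 * dt) / lam2

    inv = 1.0 / disc
    # e^{A dt} entries
    e11 = (f1 * (a11 - lam2) - f2 * (a11 - lam1)) * inv
    e12 = (f1 - f2) * a12 * inv
    e21 = (f1 - f2) * a21 * inv
    e22 = (f1 * (a22 - lam2) - f2 * (a22 - lam1)) * inv
    # int e^{As} ds entries (first column only: b = (I/V1, 0))
    g11 = (p1_1 * (a11 - lam2) - p1_2 * (a11 - lam1)) * inv
    g21 = (p1_1 - p1_2) * a21 * inv

    u = rate / v1
    ca_end = e11 * ca + e12 * cb + g11 * u
    cb_end = e21 * ca + e22 * cb + g21 * u
    if not want_auc:
        return ca_end, cb_end

    p2_1 = (ad.expm1(lam1 * dt) - lam1 * dt) / (lam1 * lam1)
    p2_2 = (ad.expm1(lam2 * dt) - lam2 * dt) / (lam2 * lam2)
    g12 = (p1_1 - p1_2) * a12 * inv
    h11 = (p2_1 * (a11 - lam2) - p2_2 * (a11 - lam1)) * inv
    auc = g11 * ca + g12 * cb + h11 * u
    return ca_end, cb_end, auc


def step_1c(mass, k, rate, dt, want_auc_mass: bool = False):
    """Advance the one-compartment mass M by `dt` under constant infusion.

    dM/dt = I - k M, so M(dt) = M0 e^{-k dt} + (I/k)(1 - e^{-k dt}).
    With `want_auc_mass` also returns int_0^dt M(s) ds (divide by V for the
    concentration AUC).
    """
    d = ad.expm1(-k * dt)           # e^{-k dt} - 1  (negative)
    mass_end = mass * (d + 1.0) + rate * (-d) / k
    if not want_auc_mass:
        return mass_end
    # int M = M0 (1-e^{-k dt})/k + (I/k)(dt - (1-e^{-k dt})/k)
    w = -d / k
    auc_mass = mass * w + (rate / k) * (dt - w)
    return mass_end, auc_mass
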
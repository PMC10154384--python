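"""AFM nanoindentation: Hertz-model stiffness of single cells.

A force–distance curve acquired with a spherical probe (a polystyrene bead of
radius R glued to the cantilever) is reduced to a Young's modulus E via the
spherical Hertz contact model

    F(δ) = (4/3) · E/(1−ν²) · √R · δ^{3/2},   δ = z − z_contact,

valid for small indentations (δ ≲ 0.1 R) of an elastic half-space with
Poisson ratio ν (0.5 for an incompressible cell). The pipeline is a linear
baseline correction on the pre-contact segment, a contact-point search by
piecewise-model residual minimisation over the sampled z grid, and a linear
least-squares fit of E on the windowed post-contact data (the model is
linear in E once the contact point is fixed).

Units: z and R in µm, forces in nN, E in Pa.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

__all__ = [
    "IndentationCurve",
    "HertzFit",
    "hertz_force",
    "baseline_correct",
    "find_contact_point",
    "hertz_fit",
    "fit_curve",
]

#: Unit factor: E [Pa] · √(R [µm]) · δ^{3/2} [µm^{3/2}] → force in nN.
_UNIT = 1e-3


def hertz_force(
    delta_um: np.ndarray, E_pa: float, R_um: float, nu: float = 0.5
) -> np.ndarray:
    """Spherical-indenter Hertz force (nN) at indentation depth δ (µm)."""
    d = np.clip(np.asarray(delta_um, dtype=float), 0.0, None)
    return (4.0 / 3.0) * (E_pa / (1.0 - nu**2)) * np.sqrt(R_um) * d**1.5 * _UNIT


@dataclass
class IndentationCurve:
    """One approach force curve.

    ``z_um`` is the piezo extension toward the cell (strictly monotone
    increasing means approaching/indenting); ``force_nN`` the cantilever
    force. ``cantilever_k`` in N/m is carried for deflection→force
    conversion done at load time and is not used by the fit itself.
    """

    z_um: np.ndarray
    force_nN: np.ndarray
    probe_radius_um: float = 7.5
    cantilever_k: float = 0.03
    poisson_nu: float = 0.5

    def __post_init__(self) -> None:
        self.z_um = np.asarray(self.z_um, dtype=float)
        self.force_nN = np.asarray(self.force_nN, dtype=float)
        dz = np.diff(self.z_um)
        if len(dz) and not (np.all(dz > 0) or np.all(dz < 0)):
            raise ValueError("z must be strictly monotone")
        if not np.all(np.isfinite(self.force_nN)):
            raise ValueError("forces must be finite")
        if self.probe_radius_um <= 0:
            raise ValueError("probe radius must be positive")


@dataclass
class HertzFit:
    E_pa: float | None
    contact_z_um: float | None
    rss: float
    fit_window_um: float
    converged: bool
    no_contact: bool = False


def baseline_correct(
    curve: IndentationCurve, pre_contact_fraction: float = 0.3
) -> IndentationCurve:
    """Remove the linear pre-contact baseline (drift / virtual deflection).

    Fits a straight line to the first ``pre_contact_fraction`` of samples
    (assumed pre-contact) and subtracts it from the whole curve; the
    operation is idempotent up to floating point.
    """
    if not 0 < pre_contact_fraction < 1:
        raise ValueError("pre_contact_fraction must be in (0, 1)")
    n = int(len(curve.z_um) * pre_contact_fraction)
    if n < 10:
        raise ValueError(f"only {n} pre-contact samples (need >= 10)")
    coef = np.polyfit(curve.z_um[:n], curve.force_nN[:n], 1)
    corrected = curve.force_nN - np.polyval(coef, curve.z_um)
    return replace(curve, force_nN=corrected)


def _fit_E_linear(
    delta: np.ndarray, force: np.ndarray, R: float, nu: float
) -> tuple[float, float]:
    """Closed-form least-squares E (Pa) and RSS given fixed contact point."""
    g = (4.0 / 3.0) / (1.0 - nu**2) * np.sqrt(R) * delta**1.5 * _UNIT
    denom = float(g @ g)
    if denom == 0:
        return 0.0, float(force @ force)
    E = float(g @ force) / denom
    E = max(E, 0.0)
    resid = force - E * g
    return E, float(resid @ resid)


def find_contact_point(
    curve: IndentationCurve,
    max_indentation_um: float | None = None,
    min_improvement: float = 0.02,
) -> float:
    """Contact point by piecewise-model grid search.

    Every sampled z is a candidate contact point; the model is zero force
    before contact and the Hertz form after, with E profiled out in closed
    form. The candidate minimising the total residual over the whole
    (baseline-corrected) curve wins. If the best candidate does not improve
    on the flat (no-contact) model by at least ``min_improvement``
    (fractional RSS reduction), a no-contact condition is reported.
    """
    z = curve.z_um
    f = curve.force_nN
    if max_indentation_um is None:
        max_indentation_um = 0.1 * curve.probe_radius_um
    rss_flat = float(f @ f)
    best = (np.inf, None)
    for i in range(len(z) - 5):
        zc = z[i]
        delta = z - zc
        post = delta > 0
        fit_sel = post & (delta <= max_indentation_um)
        if fit_sel.sum() < 5:
            continue
        E, _ = _fit_E_linear(delta[fit_sel], f[fit_sel], curve.probe_radius_um,
                             curve.poisson_nu)
        model = np.zeros_like(f)
        model[post] = hertz_force(delta[post], E, curve.probe_radius_um,
                                  curve.poisson_nu)
        # total residual over the whole curve: a too-early candidate fits
        # E ≈ 0 on its (pre-contact) window and is punished by the real rise
        r = f - model
        rss = float(r @ r)
        if rss < best[0]:
            best = (rss, zc)
    if best[1] is None or rss_flat == 0 or (
        (rss_flat - best[0]) / rss_flat < min_improvement
    ):
        raise ValueError("no contact detected: flat model is adequate")
    return float(best[1])


def hertz_fit(
    curve: IndentationCurve,
    contact_z_um: float,
    max_indentation_um: float | None = None,
) -> HertzFit:
    """Least-squares Hertz fit of E on the post-contact window.

    ``max_indentation_um`` caps the fitted indentation depth (default 10% of
    the bead radius, the usual Hertz validity bound).
    """
    if max_indentation_um is None:
        max_indentation_um = 0.1 * curve.probe_radius_um
    delta = curve.z_um - contact_z_um
    sel = (delta > 0) & (delta <= max_indentation_um)
    if sel.sum() < 20:
        return HertzFit(
            E_pa=None,
            contact_z_um=contact_z_um,
            rss=np.nan,
            fit_window_um=max_indentation_um,
            converged=False,
        )
    E, rss = _fit_E_linear(
        delta[sel], curve.force_nN[sel], curve.probe_radius_um, curve.poisson_nu
    )
    return HertzFit(
        E_pa=E,
        contact_z_um=contact_z_um,
        rss=rss,
        fit_window_um=max_indentation_um,
        converged=E > 0,
    )


def fit_curve(
    curve: IndentationCurve,
    pre_contact_fraction: float = 0.3,
    max_indentation_um: float | None = None,
) -> HertzFit:
    """Full per-curve pipeline: baseline, contact point, Hertz fit."""
    corr = baseline_correct(curve, pre_contact_fraction)
    try:
        zc = find_contact_point(corr, max_indentation_um)
    except ValueError:
        return HertzFit(
            E_pa=None,
            contact_z_um=None,
            rss=np.nan,
            fit_window_um=max_indentation_um or 0.1 * curve.probe_radius_um,
            converged=False,
            no_contact=True,
        )
    return hertz_fit(corr, zc, max_indentation_um)
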
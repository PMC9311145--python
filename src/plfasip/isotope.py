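"""δ¹³C ⇄ atom-fraction conversion and FAME derivative-carbon correction.

δ¹³C expresses the ¹³C/¹²C ratio of a sample relative to the PDB
standard ratio (0.01118):

    δ = (R_sample / R_PDB − 1) × 1000   [‰]

Isotope mass balance is linear in *atom fraction* F = ¹³C / (¹³C + ¹²C)
= R / (1 + R), not in δ, so the mixing algebra elsewhere in the package
works in atom fraction.  At natural abundance δ of ±50 ‰ the two scales
are nearly proportional; at the 6.7–8.0 atom % enrichment of labelled
residues (δ > 5000 ‰) the distinction matters.

Methanolysis adds one methanol-derived carbon to each fatty acid, so a
measured FAME δ blends the lipid signal with the methanol signal.  The
standard correction removes it by carbon-weighted mass balance.
"""

from __future__ import annotations

import numpy as np

from .datamodel import IsotopeConstants

__all__ = [
    "delta_to_atom_fraction",
    "atom_fraction_to_delta",
    "correct_fame_to_plfa",
    "correct_fame_atom_fraction",
]

_DEFAULT = IsotopeConstants()


def delta_to_atom_fraction(delta, constants: IsotopeConstants = _DEFAULT):
    """Atom fraction ¹³C from δ¹³C (‰ vs PDB).

    Accepts scalars or arrays.  δ = −1000 ‰ means zero ¹³C; values below
    −1000 ‰ would imply a negative isotope ratio and raise.
    """
    delta = np.asarray(delta, dtype=float)
    if np.any(delta < -1000.0):
        raise ValueError("δ¹³C below −1000 ‰ implies a negative isotope ratio")
    r = constants.r_pdb * (1.0 + delta / 1000.0)
    f = r / (1.0 + r)
    return float(f) if f.ndim == 0 else f


def atom_fraction_to_delta(f, constants: IsotopeConstants = _DEFAULT):
    """δ¹³C (‰ vs PDB) from atom fraction ¹³C; exact inverse of
    :func:`delta_to_atom_fraction`."""
    f = np.asarray(f, dtype=float)
    if np.any(f < 0.0) or np.any(f >= 1.0):
        raise ValueError("atom fraction must lie in [0, 1)")
    r = f / (1.0 - f)
    delta = (r / constants.r_pdb - 1.0) * 1000.0
    return float(delta) if delta.ndim == 0 else delta


def correct_fame_to_plfa(delta_fame, n_carbon, delta_methanol):
    """Remove the methanol-derived carbon from a FAME δ¹³C value.

    The methyl ester of an ``n_carbon``-carbon fatty acid contains
    ``n_carbon + 1`` carbons, one of which comes from the derivatization
    methanol.  Carbon-weighted mass balance in δ space gives

        δ_PLFA = ((n + 1) · δ_FAME − δ_MeOH) / n

    which amplifies |δ_FAME − δ_MeOH| by (n + 1)/n and is the identity
    when the two δ values coincide.
    """
    delta_fame = np.asarray(delta_fame, dtype=float)
    n = np.asarray(n_carbon, dtype=float)
    if np.any(n < 2):
        raise ValueError("n_carbon must be >= 2")
    out = ((n + 1.0) * delta_fame - float(delta_methanol)) / n
    return float(out) if out.ndim == 0 else out


def correct_fame_atom_fraction(
    f_fame, n_carbon, delta_methanol, constants: IsotopeConstants = _DEFAULT
):
    """Exact atom-fraction-space derivative correction.

    Solves (n + 1) · F_FAME = n · F_PLFA + F_MeOH for F_PLFA.  At
    tracer-level enrichment this differs negligibly from converting the
    δ-space correction, but it is the exact isotope mass balance and is
    exposed as an alternative behind the pipeline's
    ``correction_space`` switch.
    """
    f_fame = np.asarray(f_fame, dtype=float)
    n = np.asarray(n_carbon, dtype=float)
    if np.any(n < 2):
        raise ValueError("n_carbon must be >= 2")
    f_meoh = delta_to_atom_fraction(float(delta_methanol), constants)
    out = ((n + 1.0) * f_fame - f_meoh) / n
    return float(out) if out.ndim == 0 else out
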
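"""Reduced-unit conventions and physical conversion constants.

The simulation works in reduced units: energy in kBT (kBT = 1), length in
monomer diameters sigma (sigma = 1), mass m = 1 and time tau = sigma *
sqrt(m / kBT).  One monomer coarse-grains 10 bp of B-form DNA, so sigma maps
to 3.4 nm (10 bp x 0.34 nm/bp).  With kBT = 4.11 pN nm (room temperature),
one kBT/sigma of force is ~1.209 pN.
"""

from __future__ import annotations

AVOGADRO = 6.02214076e23  # 1/mol

#: physical size of one bead (10 bp of DNA), nm
SIGMA_NM = 3.4

#: thermal energy at room temperature, pN nm
KBT_PN_NM = 4.11

#: force conversion: 1 kBT/sigma in pN
PN_PER_KBT_SIGMA = KBT_PN_NM / SIGMA_NM  # ~1.2088


def box_volume_liters(box: tuple[float, float, float], sigma_nm: float = SIGMA_NM) -> float:
    """Volume of a simulation box given in sigma units, converted to liters."""
    lx, ly, lz = box
    if lx <= 0 or ly <= 0 or lz <= 0:
        raise ValueError(f"box dimensions must be positive, got {box}")
    v_nm3 = lx * ly * lz * sigma_nm**3
    return v_nm3 * 1e-24  # 1 nm^3 = 1e-24 L


def concentration_to_count(rho_um: float, box: tuple[float, float, float],
                           sigma_nm: float = SIGMA_NM) -> int:
    """Number of protein beads realizing a bulk concentration ``rho_um`` (uM).

    Np = round(rho * N_A * V) with V the box volume in liters.
    """
    if rho_um < 0:
        raise ValueError(f"concentration must be non-negative, got {rho_um}")
    if sigma_nm <= 0:
        raise ValueError(f"sigma_nm must be positive, got {sigma_nm}")
    return int(round(rho_um * 1e-6 * AVOGADRO * box_volume_liters(box, sigma_nm)))


def count_to_concentration(n: int, box: tuple[float, float, float],
                           sigma_nm: float = SIGMA_NM) -> float:
    """Bulk concentration (uM) realized by ``n`` proteins in ``box``."""
    if n < 0:
        raise ValueError(f"count must be non-negative, got {n}")
    return n / (AVOGADRO * box_volume_liters(box, sigma_nm)) * 1e6
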
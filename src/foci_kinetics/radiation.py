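"""Radiation-quality metadata.

A radiation quality is an ion species at a nominal beam energy; the LET at
the cell-nucleus midplane (computed externally with a transport code) is
carried along as metadata only — it labels rows of the fit report and never
enters the kinetic model.
"""

from __future__ import annotations

from dataclasses import dataclass


@dataclass(frozen=True)
class RadiationQuality:
    """One ion beam used for targeted irradiation.

    Parameters
    ----------
    label
        Short identifier used as the key in datasets, spectra and fit
        reports (e.g. ``"p_3MeV"``).
    particle
        Ion species (``"proton"`` or ``"alpha"``).
    beam_energy_mev
        Nominal beam energy in MeV, before energy loss in the exit window
        and dish foil.
    let_kev_um
        Unrestricted linear energy transfer at the nucleus centre, keV/µm.
    let_sd_kev_um
        Stated uncertainty of the LET value, keV/µm.
    """

    label: str
    particle: str
    beam_energy_mev: float
    let_kev_um: float
    let_sd_kev_um: float = 0.0


#: The four beams of the HUVEC microbeam experiment this package models:
#: one proton beam and three alpha-particle beams spanning 19–170 keV/µm.
DEFAULT_QUALITIES: tuple[RadiationQuality, ...] = (
    RadiationQuality("p_3MeV", "proton", 3.0, 19.0, 2.0),
    RadiationQuality("a_20MeV", "alpha", 20.0, 36.0, 1.0),
    RadiationQuality("a_10MeV", "alpha", 10.0, 85.0, 4.0),
    RadiationQuality("a_8MeV", "alpha", 8.0, 170.0, 40.0),
)


def quality_by_label(label: str) -> RadiationQuality:
    for q in DEFAULT_QUALITIES:
        if q.label == label:
            return q
    raise KeyError(f"unknown radiation quality {label!r}")
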
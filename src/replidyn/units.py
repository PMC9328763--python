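"""Concentration unit conversions.

Mass concentrations from quantitative western blots (ng/µl) are converted
to molar concentrations via the protein's molecular mass:

    c [nM] = (ng/µl) / MW [kDa] * 1e3

since 1 ng/µl = 1 mg/l = 1e-3 g/l and 1 kDa = 1e3 g/mol. Xenopus Yap runs
at ~65 kDa, giving 11 ng/µl ≈ 169 nM in S-phase egg extract.
"""

from __future__ import annotations

__all__ = ["YAP_MW_KDA", "molar_nM_from_mass", "mass_ng_per_ul_from_molar"]

YAP_MW_KDA = 65.0  # Xenopus laevis Yap1, kDa


def molar_nM_from_mass(ng_per_ul: float, mw_kda: float) -> float:
    """Molar concentration (nM) from mass concentration (ng/µl) and MW (kDa)."""
    if ng_per_ul < 0:
        raise ValueError("mass concentration must be >= 0")
    if mw_kda <= 0:
        raise ValueError("molecular mass must be > 0")
    return ng_per_ul / mw_kda * 1e3


def mass_ng_per_ul_from_molar(nM: float, mw_kda: float) -> float:
    """Mass concentration (ng/µl) from molar concentration (nM) and MW (kDa)."""
    if nM < 0:
        raise ValueError("molar concentration must be >= 0")
    if mw_kda <= 0:
        raise ValueError("molecular mass must be > 0")
    return nM * mw_kda / 1e3
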
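"""Synthetic LC-MS peak lists: jittered reference standards plus decoys.

The built-in reference table holds 13 compounds (flavonoids, saponins,
alkaloids, phenolic acids, coumarins) typical of Gegen Qinlian and Pulsatilla
decoction fractions. Adduct m/z values are computed at run time from the
molecular formulas (monoisotopic, [M+H]+ / [M-H]-, with the quaternary
alkaloids measured as intact [M]+ cations); retention times are synthetic
placeholders, not measured values.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from pyteomics import mass as _mass

__all__ = ["default_reference_standards", "generate_peaklist", "SCAN_RANGE"]

SCAN_RANGE = (100.0, 2000.0)  # acquisition m/z bounds
_PROTON = 1.007276466812

# name -> (molecular formula, ion mode, cationic). Quaternary alkaloids
# (berberine, palmatine, phellodendrine) carry a fixed positive charge; their
# formulas below are the cation's and no proton is added.
_COMPOUNDS: dict[str, tuple[str, str, bool]] = {
    "baicalin": ("C21H18O11", "negative", False),
    "daidzin": ("C21H20O9", "negative", False),
    "3'-methoxypuerarin": ("C22H22O10", "positive", False),
    "oroxindin": ("C22H20O11", "negative", False),
    "glycyrrhizic acid": ("C42H62O16", "negative", False),
    "puerarin": ("C21H20O9", "positive", False),
    "oroxyloside": ("C22H20O11", "negative", False),
    "esculin": ("C15H16O9", "negative", False),
    "fraxin": ("C16H18O10", "negative", False),
    "phellodendrine": ("C20H24NO4", "positive", True),
    "palmatine": ("C21H22NO4", "positive", True),
    "berberine": ("C20H18NO4", "positive", True),
    "chlorogenic acid": ("C16H18O9", "negative", False),
}


def default_reference_standards() -> pd.DataFrame:
    """Reference-standard table: name, mz, rt, ion_mode.

    Synthetic stand-in for a bench reference list: m/z is the exact
    monoisotopic adduct mass; rt values are invented, evenly spread over a
    15-minute gradient in a fixed order.
    """
    rows = []
    for i, (name, (formula, mode, cationic)) in enumerate(sorted(_COMPOUNDS.items())):
        m = _mass.calculate_mass(formula=formula)
        if cationic:
            mz = m - 5.48579909e-4  # intact cation: neutral-formula mass minus one electron
        elif mode == "positive":
            mz = m + _PROTON
        else:
            mz = m - _PROTON
        rows.append(
            {
                "name": name,
                "mz": round(float(mz), 5),
                "rt": round(1.0 + i * 14.0 / max(len(_COMPOUNDS) - 1, 1), 3),
                "ion_mode": mode,
            }
        )
    return pd.DataFrame(rows)


def generate_peaklist(
    references: pd.DataFrame,
    mz_jitter_ppm: float = 3.0,
    rt_jitter_min: float = 0.05,
    decoys: int = 0,
    seed: int = 0,
    tolerance_ppm: float = 10.0,
    scan_range: tuple[float, float] = SCAN_RANGE,
) -> pd.DataFrame:
    """Observed peaks: one jittered copy per reference plus unmatched decoys.

    The m/z jitter magnitude is drawn uniformly in
    [mz_jitter_ppm/2, mz_jitter_ppm] with a random sign, so the nominal
    jitter level is representative of the errors rather than an upper tail;
    rt jitter is drawn the same way. Decoys land at least
    ``3 * tolerance_ppm`` away from every reference m/z and inside
    ``scan_range``. Returns columns mz, rt, intensity, ion_mode, is_decoy,
    source (the originating reference name, or "" for decoys).
    """
    if len(references) == 0:
        raise ValueError("references must be non-empty")
    if mz_jitter_ppm < 0 or rt_jitter_min < 0:
        raise ValueError("jitters must be >= 0")
    if decoys < 0:
        raise ValueError("decoys must be >= 0")

    rng = np.random.default_rng(seed)
    rows = []
    for _, ref in references.iterrows():
        if not (scan_range[0] <= ref["mz"] <= scan_range[1]):
            raise ValueError(
                f"reference {ref['name']!r} m/z {ref['mz']} outside scan range {scan_range}"
            )
        mz_off = rng.uniform(mz_jitter_ppm / 2, mz_jitter_ppm) * rng.choice([-1.0, 1.0])
        rt_off = rng.uniform(rt_jitter_min / 2, rt_jitter_min) * rng.choice([-1.0, 1.0])
        rows.append(
            {
                "mz": float(ref["mz"] * (1 + mz_off * 1e-6)),
                "rt": max(0.0, float(ref["rt"] + rt_off)),
                "intensity": float(np.round(rng.uniform(1e4, 1e6), 1)),
                "ion_mode": ref["ion_mode"],
                "is_decoy": False,
                "source": ref["name"],
            }
        )

    ref_mz = references["mz"].to_numpy(dtype=float)
    min_sep = 3.0 * tolerance_ppm
    placed = 0
    for _try in range(1000 * max(decoys, 1)):
        if placed == decoys:
            break
        mz = float(rng.uniform(*scan_range))
        ppm_dist = np.abs(mz - ref_mz) / ref_mz * 1e6
        if ppm_dist.min() < min_sep:
            continue
        rows.append(
            {
                "mz": mz,
                "rt": float(np.round(rng.uniform(0.5, 15.5), 3)),
                "intensity": float(np.round(rng.uniform(1e3, 1e5), 1)),
                "ion_mode": str(rng.choice(["positive", "negative"])),
                "is_decoy": True,
                "source": "",
            }
        )
        placed += 1
    if placed < decoys:
        raise RuntimeError(
            f"could not place {decoys} decoys >= {min_sep} ppm from all references "
            f"within scan range {scan_range}"
        )
    return pd.DataFrame(rows)
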
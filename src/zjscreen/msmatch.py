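"""LC-MS peak matching against reference standards.

Observed peaks are assigned to reference standards of the same ion mode when
both the relative mass error (ppm) and the retention-time difference fall
within tolerance. Assignment is greedy and one-to-one: candidate pairs are
taken in order of |ppm error| (ties: smaller |rt error|, then reference
name), and a pair is accepted only if neither the observed peak nor the
reference has been used. Greedy nearest-ppm was chosen over a global optimal
assignment for transparency; with tolerances well below reference spacing
the two coincide.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

__all__ = ["PeakMatch", "MatchResult", "ppm_error", "match_peaks"]

DEFAULT_MZ_TOL_PPM = 10.0
DEFAULT_RT_TOL_MIN = 0.2


def ppm_error(obs_mz: float, ref_mz: float) -> float:
    """(observed - reference) / reference * 1e6."""
    if ref_mz <= 0:
        raise ValueError(f"reference m/z must be > 0, got {ref_mz}")
    return (obs_mz - ref_mz) / ref_mz * 1e6


@dataclass(frozen=True)
class PeakMatch:
    observed_index: int
    reference_name: str
    obs_mz: float
    ref_mz: float
    ppm_error: float
    rt_error: float


@dataclass
class MatchResult:
    matches: list[PeakMatch]
    unmatched_observed: list[int]      # row indices into the observed table
    unmatched_references: list[str]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "observed_index": [m.observed_index for m in self.matches],
                "reference_name": [m.reference_name for m in self.matches],
                "obs_mz": [m.obs_mz for m in self.matches],
                "ref_mz": [m.ref_mz for m in self.matches],
                "ppm_error": [m.ppm_error for m in self.matches],
                "rt_error": [m.rt_error for m in self.matches],
            }
        )


def match_peaks(
    observed: pd.DataFrame,
    references: pd.DataFrame,
    mz_tol_ppm: float = DEFAULT_MZ_TOL_PPM,
    rt_tol: float = DEFAULT_RT_TOL_MIN,
) -> MatchResult:
    """Match observed peaks (mz, rt, ion_mode) to references (name, mz, rt, ion_mode).

    Matching is restricted to equal ion mode; each observed peak and each
    reference appears in at most one match.
    """
    if mz_tol_ppm <= 0 or rt_tol <= 0:
        raise ValueError(f"tolerances must be > 0, got {mz_tol_ppm} ppm, {rt_tol} min")
    for col in ("mz", "rt", "ion_mode"):
        if col not in observed.columns:
            raise ValueError(f"observed table is missing column {col!r}")
        if col not in references.columns:
            raise ValueError(f"reference table is missing column {col!r}")
    if "name" not in references.columns:
        raise ValueError("reference table is missing column 'name'")

    candidates = []
    for oi, obs in observed.reset_index(drop=True).iterrows():
        for _, ref in references.iterrows():
            if obs["ion_mode"] != ref["ion_mode"]:
                continue
            ppm = ppm_error(float(obs["mz"]), float(ref["mz"]))
            dt = float(obs["rt"]) - float(ref["rt"])
            if abs(ppm) <= mz_tol_ppm and abs(dt) <= rt_tol:
                candidates.append((abs(ppm), abs(dt), str(ref["name"]), oi, ppm, dt,
                                   float(obs["mz"]), float(ref["mz"])))
    candidates.sort(key=lambda c: (c[0], c[1], c[2]))

    used_obs: set[int] = set()
    used_ref: set[str] = set()
    matches: list[PeakMatch] = []
    for _app, _adt, name, oi, ppm, dt, omz, rmz in candidates:
        if oi in used_obs or name in used_ref:
            continue
        used_obs.add(oi)
        used_ref.add(name)
        matches.append(
            PeakMatch(
                observed_index=oi,
                reference_name=name,
                obs_mz=omz,
                ref_mz=rmz,
                ppm_error=ppm,
                rt_error=dt,
            )
        )
    matches.sort(key=lambda m: m.observed_index)

    unmatched_obs = [i for i in range(len(observed)) if i not in used_obs]
    unmatched_ref = sorted(set(references["name"].astype(str)) - used_ref)
    return MatchResult(
        matches=matches,
        unmatched_observed=unmatched_obs,
        unmatched_references=unmatched_ref,
    )
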
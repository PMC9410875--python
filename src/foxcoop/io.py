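"""Tabular I/O for EMSA titrations, ITC traces, groove profiles and motif hits.

Concentrations are molar inside the package; tables use micromolar columns
(suffix ``_uM``) to match how bench titrations are recorded.
"""

from __future__ import annotations

from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .binding_model import SpeciesFractions, TitrationLane
from .itc_model import ITCTrace
from .sequence_motif import DnaSequence, MotifMatch, SitePair
from .structure_groove import GrooveProfile

__all__ = [
    "read_emsa_table",
    "write_emsa_table",
    "read_itc_trace",
    "write_itc_trace",
    "write_groove_profile",
    "write_motif_hits",
]

EMSA_COLUMNS = ["lane", "p_total_uM", "d_total_uM", "f_free", "f_mono", "f_dimer"]
#: Fractions summing to 1 within this tolerance are renormalized on read.
FRACTION_SUM_TOL = 0.02


def write_emsa_table(lanes: Sequence[TitrationLane], path: str | Path) -> None:
    df = pd.DataFrame(
        {
            "lane": [ln.label or f"lane{i + 1}" for i, ln in enumerate(lanes)],
            "p_total_uM": [ln.p_total * 1e6 for ln in lanes],
            "d_total_uM": [ln.d_total * 1e6 for ln in lanes],
            "f_free": [ln.fractions.f0 for ln in lanes],
            "f_mono": [ln.fractions.f1 for ln in lanes],
            "f_dimer": [ln.fractions.f2 for ln in lanes],
        }
    )
    df.to_csv(path, sep="\t", index=False, float_format="%.10g")


def read_emsa_table(path: str | Path) -> list[TitrationLane]:
    """Read an EMSA TSV; fractions are renormalized if they sum to 1 +/- 0.02."""
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in EMSA_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    lanes = []
    for _, row in df.iterrows():
        fracs = np.array([row.f_free, row.f_mono, row.f_dimer], dtype=float)
        total = fracs.sum()
        if abs(total - 1.0) > FRACTION_SUM_TOL:
            raise ValueError(
                f"{path}: lane {row.lane!r} fractions sum to {total:.4f}, "
                f"outside 1 +/- {FRACTION_SUM_TOL}"
            )
        fracs = fracs / total
        lanes.append(
            TitrationLane(
                p_total=float(row.p_total_uM) * 1e-6,
                d_total=float(row.d_total_uM) * 1e-6,
                fractions=SpeciesFractions(*fracs),
                label=str(row.lane),
            )
        )
    return lanes


def write_itc_trace(trace: ITCTrace, path: str | Path) -> None:
    df = pd.DataFrame(
        {
            "injection": np.arange(1, trace.n_injections + 1),
            "injectant_nmol": trace.injectant_moles * 1e9,
            "heat_ucal": trace.heats_ucal,
            "normalized_kcal_per_mol": trace.normalized_kcal_per_mol,
            "molar_ratio": trace.molar_ratio,
            "cumulative_kcal": trace.cumulative_kcal,
        }
    )
    df.to_csv(path, sep="\t", index=False, float_format="%.10g")


def read_itc_trace(path: str | Path) -> ITCTrace:
    df = pd.read_csv(path, sep="\t")
    required = [
        "injectant_nmol",
        "heat_ucal",
        "normalized_kcal_per_mol",
        "molar_ratio",
        "cumulative_kcal",
    ]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    return ITCTrace(
        injectant_moles=df["injectant_nmol"].to_numpy() * 1e-9,
        heats_ucal=df["heat_ucal"].to_numpy(dtype=float),
        normalized_kcal_per_mol=df["normalized_kcal_per_mol"].to_numpy(dtype=float),
        molar_ratio=df["molar_ratio"].to_numpy(dtype=float),
        cumulative_kcal=df["cumulative_kcal"].to_numpy(dtype=float),
    )


def write_groove_profile(profile: GrooveProfile, path: str | Path) -> None:
    df = pd.DataFrame(
        {
            "level": [lv.level for lv in profile.levels],
            "ref_res": [lv.ref_resid for lv in profile.levels],
            "partner_res": [lv.partner_resid for lv in profile.levels],
            "pp_dist_A": [lv.raw_distance for lv in profile.levels],
            "width_A": [lv.width for lv in profile.levels],
        }
    )
    df.to_csv(path, sep="\t", index=False, float_format="%.4f")


def write_motif_hits(
    seq: DnaSequence,
    matches: Sequence[MotifMatch],
    pairs: Sequence[SitePair],
    path: str | Path,
) -> None:
    """Hits TSV: one row per match, pair membership annotated."""
    pair_of: dict[tuple[int, int, str], tuple[int, int]] = {}
    for pid, pair in enumerate(pairs, start=1):
        for m in (pair.primary, pair.secondary):
            pair_of.setdefault((m.start, m.end, m.strand), (pid, pair.overlap))
    rows = []
    seen = set()
    for m in list(matches) + [x for p in pairs for x in (p.primary, p.secondary)]:
        key = (m.start, m.end, m.strand, m.pattern_name)
        if key in seen:
            continue
        seen.add(key)
        pid, overlap = pair_of.get((m.start, m.end, m.strand), ("", ""))
        rows.append(
            {
                "seq_id": seq.id,
                "start": m.start,
                "end": m.end,
                "strand": m.strand,
                "site": m.site,
                "pattern": m.pattern_name,
                "pair_id": pid,
                "overlap": overlap,
            }
        )
    pd.DataFrame(
        rows,
        columns=["seq_id", "start", "end", "strand", "site", "pattern", "pair_id", "overlap"],
    ).to_csv(path, sep="\t", index=False)
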
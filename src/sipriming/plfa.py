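"""¹³C incorporation into phospholipid fatty acid (PLFA) biomarkers.

PLFAs are membrane lipids used as viable-biomass proxies; their δ¹³C
reveals which microbial groups assimilated a ¹³C-labelled substrate.
This module computes per-PLFA incorporation (I_PLFA = E × concentration
/ substrate atom fraction), biomarker-group totals, proportional
enrichment profiles (I_PLFA / I_total), the low-enrichment filter, and
the empirical logit transform that feeds the PLS analysis.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .isotope import SubstrateSpec, excess_13c

logger = logging.getLogger(__name__)

__all__ = [
    "canonical_plfa",
    "BiomarkerMap",
    "default_biomarker_map",
    "C18_PUFA",
    "plfa_incorporation",
    "group_incorporation",
    "relative_enrichment",
    "enrichment_matrix",
    "filter_low_enrichment",
    "empirical_logit",
]

#: C18 polyunsaturated fatty acids counted as microeukaryote biomarkers.
#: The set is configurable; this default covers the common ω6/ω3 C18 PUFAs.
C18_PUFA = ("18:2w6", "18:3w3", "18:3w6")

# Input-dialect aliases, applied after ω→w normalisation.
_ALIASES = {
    "i-15:0": "i15:0",
    "a-15:0": "a15:0",
    "i-16:0": "i16:0",
    "10me16:0": "10Me16:0",
}

_N_NOTATION = re.compile(r"^(?P<head>.*\d+:\d+)n(?P<pos>\d+.*)$")


def canonical_plfa(name: str) -> str:
    """Normalise a PLFA name to the package's canonical dialect.

    ω (and Ω) become ``w``; ``18:1n7``-style n-notation becomes
    ``18:1w7``; hyphenated branch prefixes are collapsed (``i-15:0`` →
    ``i15:0``); ``cy17:0`` and ``10Me16:0`` are preserved verbatim.
    """
    s = name.strip().replace("ω", "w").replace("Ω", "w").replace("ω", "w")
    if s.lower() in _ALIASES:
        return _ALIASES[s.lower()]
    m = _N_NOTATION.match(s)
    if m:
        s = f"{m.group('head')}w{m.group('pos')}"
    return s


@dataclass(frozen=True)
class BiomarkerMap:
    """Disjoint taxonomic biomarker groups of PLFA names."""

    groups: Mapping[str, tuple[str, ...]]

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for group, members in self.groups.items():
            canon = {canonical_plfa(m) for m in members}
            overlap = seen & canon
            if overlap:
                raise ValueError(
                    f"biomarker groups must be disjoint; {sorted(overlap)} repeated in {group!r}"
                )
            seen |= canon

    def members(self, group: str) -> tuple[str, ...]:
        return tuple(canonical_plfa(m) for m in self.groups[group])


def default_biomarker_map(c18_pufa: Iterable[str] = C18_PUFA) -> BiomarkerMap:
    """Bacterial (i15:0, a15:0, i16:0, 18:1ω7) and microeukaryote
    (C18 PUFA + 18:1ω9) biomarker groups."""
    return BiomarkerMap(
        {
            "bacteria": ("i15:0", "a15:0", "i16:0", "18:1w7"),
            "eukaryotes": tuple(c18_pufa) + ("18:1w9",),
        }
    )


def _canonicalise(df: pd.DataFrame) -> pd.DataFrame:
    out = df.copy()
    out["plfa"] = out["plfa"].map(canonical_plfa)
    return out


def plfa_incorporation(
    df: pd.DataFrame,
    substrate: SubstrateSpec,
    control_treatment: str = "CTRL",
) -> pd.DataFrame:
    """Per-PLFA incorporation of substrate carbon for every labelled vial.

    ``df`` is a long table with columns vial_id, treatment, day, plfa,
    conc, delta.  The background δ for each (day, PLFA) is the mean over
    the control treatment's vials; sample PLFAs without a time-matched
    background entry are excluded with a warning.  Adds columns
    ``excess`` (atom-fraction units) and ``i_plfa`` (same unit as conc).
    """
    required = {"vial_id", "treatment", "day", "plfa", "conc", "delta"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"PLFA table is missing columns: {sorted(missing)}")
    df = _canonicalise(df)
    if df.duplicated(["vial_id", "plfa"]).any():
        raise ValueError("duplicate PLFA names within a vial profile")
    if (df["conc"] < 0).any():
        raise ValueError("PLFA concentrations must be non-negative")

    ctrl = df[df["treatment"] == control_treatment]
    if ctrl.empty:
        raise ValueError(f"no {control_treatment} profiles to define the background")
    bg = (
        ctrl.groupby(["day", "plfa"])["delta"].mean().rename("delta_background")
    )
    sample = df[df["treatment"] != control_treatment].copy()
    sample = sample.merge(bg, on=["day", "plfa"], how="left")

    orphan = sample["delta_background"].isna()
    if orphan.any():
        dropped = sorted(sample.loc[orphan, "plfa"].unique())
        logger.warning(
            "excluding PLFA(s) without time-matched background: %s", dropped
        )
        sample = sample[~orphan].copy()

    sample["excess"] = excess_13c(
        sample["delta"].to_numpy(), sample["delta_background"].to_numpy()
    )
    n_neg = int((sample["excess"] < -1e-12).sum())  # ignore float-zero noise
    if n_neg:
        logger.warning("%d PLFA entries have negative excess 13C; retained", n_neg)
    sample["i_plfa"] = (
        sample["excess"] * sample["conc"] / substrate.atom_fraction_13c
    )
    return sample


def group_incorporation(
    incorporation: pd.DataFrame, biomarker_map: BiomarkerMap | None = None
) -> pd.DataFrame:
    """Biomarker-group totals of concentration (biomass proxy) and I_PLFA.

    One row per vial × group: ``conc_total`` and ``i_total`` summed over
    the group's member PLFAs present in that vial.  An empty
    intersection yields 0 with a warning.
    """
    biomarker_map = biomarker_map or default_biomarker_map()
    rows = []
    for (vial, treatment, day), prof in incorporation.groupby(
        ["vial_id", "treatment", "day"], sort=False
    ):
        for group in biomarker_map.groups:
            members = set(biomarker_map.members(group))
            sel = prof[prof["plfa"].isin(members)]
            if sel.empty:
                logger.warning(
                    "vial %s: no PLFAs of group %r measured; total set to 0", vial, group
                )
            rows.append(
                {
                    "vial_id": vial,
                    "treatment": treatment,
                    "day": day,
                    "group": group,
                    "conc_total": float(sel["conc"].sum()),
                    "i_total": float(sel["i_plfa"].sum()),
                }
            )
    return pd.DataFrame(rows)


def relative_enrichment(incorporation: pd.DataFrame) -> pd.DataFrame:
    """Proportional enrichment I_PLFA / I_total per vial.

    I_total is the sum over *all* measured PLFAs of the vial (the
    low-enrichment filter is applied afterwards, not before
    normalisation).  Raises if a vial's I_total is not positive.
    """
    out = incorporation.copy()
    out["proportion"] = np.nan
    for vial, prof in out.groupby("vial_id", sort=False):
        total = prof["i_plfa"].sum()
        if total <= 0:
            raise ValueError(
                f"vial {vial!r}: total PLFA incorporation is not positive ({total:g})"
            )
        out.loc[prof.index, "proportion"] = prof["i_plfa"] / total
    return out


def enrichment_matrix(
    proportions: pd.DataFrame, time_average: bool = False
) -> pd.DataFrame:
    """Mean proportional-enrichment profiles as a PLFA × condition matrix.

    Columns are treatment × day combinations (or treatments only when
    ``time_average`` is on, averaging profiles over time); rows are
    PLFA names; cells are means over replicate vials (and days, when
    averaging).  Missing combinations become 0.
    """
    keys = ["treatment"] if time_average else ["treatment", "day"]
    wide = (
        proportions.groupby(keys + ["plfa"])["proportion"]
        .mean()
        .unstack(keys)  # type: ignore[arg-type]
        .fillna(0.0)
    )
    if not time_average:
        wide.columns = [f"{t}:{int(d)}" for t, d in wide.columns]
    wide.columns.name = "condition"
    wide.index.name = "plfa"
    return wide


def filter_low_enrichment(
    matrix: pd.DataFrame, threshold: float = 0.001
) -> tuple[pd.DataFrame, list[str], list[str]]:
    """Drop PLFAs whose grand-mean relative enrichment is below threshold.

    The mean is taken across all profiles (columns) entering the
    analysis; the comparison is a strict ``<``, so a mean of exactly
    ``threshold`` is retained.  Returns (filtered matrix, retained
    names, dropped names).
    """
    means = matrix.mean(axis=1)
    keep = means >= threshold
    retained = list(matrix.index[keep])
    dropped = list(matrix.index[~keep])
    if dropped:
        logger.info("dropping %d low-enrichment PLFA(s): %s", len(dropped), dropped)
    return matrix.loc[keep], retained, dropped


def empirical_logit(p, tol: float = 0.1):
    """Empirical logit ln((p + tol) / (1 − p + tol)) for proportions.

    Finite at both endpoints and antisymmetric about p = 0.5:
    f(p) + f(1 − p) = 0.  Used to normalise compositional enrichment
    profiles before PLS.
    """
    p = np.asarray(p, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("proportions must lie in [0, 1]")
    if tol <= 0:
        raise ValueError("tolerance must be positive")
    out = np.log((p + tol) / (1.0 - p + tol))
    return float(out) if np.ndim(out) == 0 else out
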
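"""Side-by-side reproduction of the published sample-size scenarios.

For every outcome the source's Results section quotes total cluster counts
at effect sizes 10% and 30%, at the outcome's text CV and at that CV minus
0.1, all at power 0.80 over a 1-year study.  ``reproduce_results`` recomputes
every such scenario (and the +0.1 CV and power-0.90 companions, for which no
totals were printed) and reports computed vs printed values with a delta.

A handful of printed values differ from the recomputed ones by 1–8 clusters
under every rounding convention tried; these are cataloged in
``KNOWN_DISCREPANCIES`` and flagged in the output rather than silently
absorbed.  The balanced-arm splits printed alongside four totals are also
checked.
"""

from __future__ import annotations

import pandas as pd

from .design import clusters_required
from .fixtures import OUTCOMES

__all__ = ["PRINTED_TOTALS", "PRINTED_SPLITS", "KNOWN_DISCREPANCIES", "reproduce_results"]

# (outcome, effect, cv, power) -> printed total clusters.  CV values are the
# 2-decimal text values and the text value minus 0.1.
PRINTED_TOTALS: dict[tuple[str, float, float, float], int] = {
    ("mrsa_bacteremia", 0.30, 0.55, 0.80): 73,
    ("mrsa_bacteremia", 0.10, 0.55, 0.80): 768,
    ("mrsa_bacteremia", 0.30, 0.45, 0.80): 60,
    ("mrsa_bacteremia", 0.10, 0.45, 0.80): 626,
    ("cauti", 0.30, 0.70, 0.80): 82,
    ("cauti", 0.10, 0.70, 0.80): 875,
    ("cauti", 0.30, 0.60, 0.80): 65,
    ("cauti", 0.10, 0.60, 0.80): 690,
    ("clabsi", 0.30, 0.55, 0.80): 60,
    ("clabsi", 0.10, 0.55, 0.80): 631,
    ("clabsi", 0.30, 0.45, 0.80): 47,
    ("clabsi", 0.10, 0.45, 0.80): 489,
    ("cdi", 0.30, 0.44, 0.80): 31,
    ("cdi", 0.10, 0.44, 0.80): 329,
    ("cdi", 0.30, 0.34, 0.80): 22,
    ("cdi", 0.10, 0.34, 0.80): 218,
    ("mrsa_acq", 0.30, 0.58, 0.80): 50,
    ("mrsa_acq", 0.10, 0.58, 0.80): 540,
    ("mrsa_acq", 0.30, 0.48, 0.80): 37,
    ("mrsa_acq", 0.10, 0.48, 0.80): 389,
    ("vre_acq", 0.30, 0.52, 0.80): 40,
    ("vre_acq", 0.10, 0.52, 0.80): 426,
    ("vre_acq", 0.30, 0.42, 0.80): 28,
    ("vre_acq", 0.10, 0.42, 0.80): 292,
}

# printed (intervention, control) arm splits, where quoted
PRINTED_SPLITS: dict[tuple[str, float, float, float], tuple[int, int]] = {
    ("mrsa_bacteremia", 0.30, 0.55, 0.80): (37, 36),
    ("cauti", 0.30, 0.70, 0.80): (41, 41),
    ("clabsi", 0.30, 0.55, 0.80): (30, 30),
    ("cdi", 0.30, 0.44, 0.80): (16, 15),
}

# Scenarios whose printed totals are off by 1-8 from the recomputed value
# under the adopted floor(c)-as-total convention (and every plausible
# alternative).  The three single-largest ones (MRSA bacteremia 10%, CAUTI
# 10%, MRSA acquisition 30%) resist all conventions; the rest are +/-1 to
# +/-8 shifts confined to the decreased-CV companions.
KNOWN_DISCREPANCIES: frozenset[tuple[str, float, float, float]] = frozenset(
    {
        ("mrsa_bacteremia", 0.10, 0.55, 0.80),
        ("cauti", 0.10, 0.70, 0.80),
        ("mrsa_acq", 0.30, 0.58, 0.80),
        ("mrsa_bacteremia", 0.10, 0.45, 0.80),
        ("cauti", 0.30, 0.60, 0.80),
        ("cauti", 0.10, 0.60, 0.80),
        ("cdi", 0.30, 0.34, 0.80),
        ("mrsa_acq", 0.10, 0.58, 0.80),
        ("mrsa_acq", 0.10, 0.48, 0.80),
        ("vre_acq", 0.10, 0.42, 0.80),
    }
)


def reproduce_results(followup_days: float = 365.0, alpha: float = 0.05) -> pd.DataFrame:
    """Recompute every published sizing scenario and compare with the text.

    Returns one row per (outcome, effect in {0.10, 0.30}, CV in {text,
    text±0.1}, power in {0.80, 0.90}) with columns: computed total and arm
    split, the printed total and split where one exists, the delta, and
    whether any mismatch is a documented discrepancy.
    """
    rows = []
    for key, fx in OUTCOMES.items():
        for effect in (0.10, 0.30):
            for dcv in (-0.1, 0.0, 0.1):
                for power in (0.80, 0.90):
                    cv = round(fx.cv_text + dcv, 10)
                    res = clusters_required(
                        fx.design_spec(
                            effect, cv=cv, followup_days=followup_days,
                            alpha=alpha, power=power,
                        )
                    )
                    scenario = (key, effect, cv, power)
                    printed = PRINTED_TOTALS.get(scenario)
                    delta = None if printed is None else res.total_clusters - printed
                    split = PRINTED_SPLITS.get(scenario)
                    rows.append(
                        {
                            "outcome": key,
                            "effect": effect,
                            "cv": cv,
                            "power": power,
                            "clusters_unrounded": res.clusters_unrounded,
                            "computed_total": res.total_clusters,
                            "computed_split": f"{res.n_intervention}/{res.n_control}",
                            "printed_total": printed,
                            "delta": delta,
                            "match": None if printed is None else delta == 0,
                            "printed_split": None if split is None else f"{split[0]}/{split[1]}",
                            "split_match": None
                            if split is None
                            else (res.n_intervention, res.n_control) == split,
                            "known_discrepancy": scenario in KNOWN_DISCREPANCIES,
                        }
                    )
    return pd.DataFrame(rows)


def unexpected_mismatches(table: pd.DataFrame) -> pd.DataFrame:
    """Rows where a printed value is missed and the miss is NOT documented."""
    cmp = table[table.printed_total.notna()]
    return cmp[(~cmp.match.astype(bool)) & (~cmp.known_discrepancy)]
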
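"""Published fitted-parameter reference panels.

These are fitted growth-model parameters for public FAERS/VigiAccess
cumulative ADR curves, as printed in the pharmacovigilance literature.
They are parameters, not raw report counts: the raw dashboards cannot be
redistributed, so worked examples regenerate noise-free curves from these
values (via :mod:`adrtrend.simulate`) rather than refitting live data.
"""

from __future__ import annotations

import numpy as np

from .series import ADRSeries

__all__ = [
    "ONCOLOGY_PANEL",
    "SATURATION_EXAMPLE",
    "LOGISTIC_EXAMPLE",
    "EXPONENTIAL_EXAMPLE",
    "oncology_panel_series",
]

# 15 active oncology drugs: exponential-model (alpha, beta) for the
# cumulative ADR curve, ordered by beta (the Detriment Index) ascending.
ONCOLOGY_PANEL: list[tuple[str, float, float]] = [
    ("Tamoxifen", 1198.5, 0.0972),
    ("Avastin", 2215.9, 0.1211),
    ("Bleomycin", 114.55, 0.139),
    ("Paclitaxel", 1526.4, 0.1673),
    ("Vincristine", 210.66, 0.1706),
    ("Methotrexate", 438.1, 0.1853),
    ("Cisplatin", 331.75, 0.1859),
    ("Doxorubicin", 922.11, 0.208),
    ("Imatinib", 661.54, 0.2427),
    ("Docetaxel", 174.39, 0.267),
    ("Rituximab", 243.38, 0.2771),
    ("Trastuzumab", 64.147, 0.3025),
    ("Revlimid", 67.908, 0.5431),
    ("Lenalidomide", 67.848, 0.5432),
    ("Pembrolizumab", 1.1524, 0.8277),
]

# Benoxaprofen (withdrawn NSAID, FAERS 1982–1999): shifted Michaelis–Menten
# saturation parameters, n = 18 annual points.
SATURATION_EXAMPLE = {
    "drug": "Benoxaprofen",
    "params": {"y0": 1106.6828, "theta1": 3694.5278, "theta2": 0.541521},
    "n_years": 18,
}

# Rofecoxib (withdrawn NSAID, FAERS 1999–2023): logistic growth-rate and
# midpoint; the upper asymptote is fitted freely, n = 25.
LOGISTIC_EXAMPLE = {
    "drug": "Rofecoxib",
    "params": {"k": 0.5513, "t0": 5.7469},
    "n_years": 25,
}

# Temazepam (VigiAccess 1980–2023): exponential fit, beta = Detriment Index.
EXPONENTIAL_EXAMPLE = {
    "drug": "Temazepam",
    "params": {"alpha": 108.5076, "beta": 0.107054},
    "n_years": 44,
}


def oncology_panel_series(n_years: int = 20, start_year: int = 2004) -> list[ADRSeries]:
    """Noise-free cumulative curves regenerated from the oncology panel.

    Each drug's curve is Y(t) = α·exp(β·t) evaluated on t = 1..n_years;
    refitting these series recovers the published β values exactly.
    """
    t = np.arange(1, n_years + 1)
    years = np.arange(start_year, start_year + n_years)
    out = []
    for drug, alpha, beta in ONCOLOGY_PANEL:
        cumulative = alpha * np.exp(beta * t)
        annual = np.diff(np.concatenate([[0.0], cumulative]))
        out.append(ADRSeries(drug_id=drug, years=years, annual_counts=annual))
    return out
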
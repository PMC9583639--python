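"""Deterministic receptor scenarios (age and sex groups) and the combined
deterministic risk table.

Adult scenarios use the Exposure Factors Handbook soil ingestion rate of
20 mg/day, exposure frequency 350 day/yr, and a 75-year exposure duration
equal to the averaging time and lifetime. Adult body weights (74.7 kg
female, 87.7 kg male, 80.8 kg combined) are calibrated defaults: they are
consistent with Exposure Factors Handbook adult means and reproduce the
published deterministic adult risks to within rounding. Child and newborn
parameters adopt Exposure Factors Handbook central values (soil-only
ingestion) and are qualitative defaults, overridable per entry.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterator, Mapping

import pandas as pd

from soilrisk.dataset_io import speciate_chromium
from soilrisk.errors import DomainError
from soilrisk.exposure import (
    DEFAULT_TOXICITY,
    ExposureScenario,
    ToxicityParams,
    average_daily_dose,
    carcinogenic_risk,
    classify_cr,
    classify_hq,
    hazard_quotient,
    lifetime_average_daily_dose,
)

ADULT_LIFETIME_YR = 75.0
ADULT_IR_MG_DAY = 20.0
EXPOSURE_FREQUENCY_DAY_YR = 350.0

#: Calibrated adult body weights, kg (female / male / combined).
ADULT_BW_KG = {"female": 74.7, "male": 87.7, "combined": 80.8}


@dataclass
class ScenarioTable:
    """Ordered collection of exposure scenarios with per-entry provenance."""

    _entries: dict[str, ExposureScenario] = field(default_factory=dict)
    _provenance: dict[str, str] = field(default_factory=dict)

    def add(self, scenario: ExposureScenario, provenance: str = "") -> None:
        if scenario.label in self._entries:
            raise DomainError(f"duplicate scenario label {scenario.label!r}")
        self._entries[scenario.label] = scenario
        self._provenance[scenario.label] = provenance

    def __getitem__(self, label: str) -> ExposureScenario:
        return self._entries[label]

    def __contains__(self, label: str) -> bool:
        return label in self._entries

    def __iter__(self) -> Iterator[ExposureScenario]:
        return iter(self._entries.values())

    def __len__(self) -> int:
        return len(self._entries)

    @property
    def labels(self) -> list[str]:
        return list(self._entries)

    def provenance(self, label: str) -> str:
        return self._provenance[label]

    def override(self, label: str, **changes) -> None:
        """Replace fields of one scenario in place (e.g. a local BW)."""
        self._entries[label] = replace(self._entries[label], **changes)

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "label": s.label, "ir": s.ir, "ef": s.ef, "ed": s.ed,
                "at": s.at, "lt": s.lt, "bw": s.bw, "cf": s.cf,
                "provenance": self._provenance[s.label],
            }
            for s in self
        ]
        return pd.DataFrame(rows)


def _adult(sex: str) -> ExposureScenario:
    return ExposureScenario(
        label=f"adult_{sex}",
        ir=ADULT_IR_MG_DAY,
        ef=EXPOSURE_FREQUENCY_DAY_YR,
        ed=ADULT_LIFETIME_YR,
        at=ADULT_LIFETIME_YR,
        lt=ADULT_LIFETIME_YR,
        bw=ADULT_BW_KG[sex],
    )


# Child groups: (label stem, IR mg/day, ED yr, {sex: BW kg}).
# IRs are Exposure Factors Handbook central soil-ingestion values; BWs are
# near EFH age-group means. Qualitative defaults, overridable.
_CHILD_GROUPS = (
    ("newborn", 30.0, 1.0, {"female": 7.5, "male": 8.0, "combined": 7.8}),
    ("child_1_6", 50.0, 5.0, {"female": 14.4, "male": 15.2, "combined": 14.8}),
    ("child_6_11", 50.0, 5.0, {"female": 31.0, "male": 32.5, "combined": 31.8}),
)


def default_scenarios() -> ScenarioTable:
    """Default receptor scenario table.

    Twelve scenarios: adults plus newborn (6 wk–1 yr), 1–6 yr and 6–11 yr
    children, each in female / male / combined variants. All use
    EF 350 day/yr, CF 1e-6 and a 75-yr lifetime; chronic averaging time
    equals exposure duration.
    """
    table = ScenarioTable()
    for sex in ("female", "male", "combined"):
        table.add(
            _adult(sex),
            provenance="EFH adult IR 20 mg/day; BW calibrated default",
        )
    for stem, ir, ed, bws in _CHILD_GROUPS:
        for sex, bw in bws.items():
            table.add(
                ExposureScenario(
                    label=f"{stem}_{sex}",
                    ir=ir,
                    ef=EXPOSURE_FREQUENCY_DAY_YR,
                    ed=ed,
                    at=ed,
                    lt=ADULT_LIFETIME_YR,
                    bw=bw,
                ),
                provenance="EFH central soil-ingestion IR and age-group BW",
            )
    return table


def scenario_risk_table(
    summaries: Mapping[str, float],
    scenarios: ScenarioTable | None = None,
    tox: Mapping[str, ToxicityParams] | None = None,
    fraction_cr6: float = 0.20,
) -> pd.DataFrame:
    """Deterministic risk table over scenarios × elements.

    Parameters
    ----------
    summaries : mapping element -> mean concentration (mg/kg)
        Total chromium ("Cr") is expanded into Cr(III) and Cr(VI) rows via
        :func:`soilrisk.dataset_io.speciate_chromium`.
    scenarios : ScenarioTable, optional
        Defaults to :func:`default_scenarios`.
    tox : mapping element form -> ToxicityParams, optional
        Defaults to :data:`soilrisk.exposure.DEFAULT_TOXICITY`.

    Returns
    -------
    pandas.DataFrame
        One row per (scenario, element form) with columns ``scenario``,
        ``element_form``, ``concentration_mg_kg``, ``add``, ``hq``,
        ``hq_zone``, ``ladd``, ``cr``, ``cr_zone``, ``flag``. A missing
        RfD or SF leaves the corresponding cells empty and sets ``flag``;
        an element with no toxicity entry at all is flagged, never dropped.
    """
    if scenarios is None:
        scenarios = default_scenarios()
    if tox is None:
        tox = DEFAULT_TOXICITY

    # expand total Cr into speciated forms
    forms: list[tuple[str, float]] = []
    for element, conc in summaries.items():
        if element == "Cr":
            cr3, cr6 = speciate_chromium(conc, fraction_cr6)
            forms.append(("Cr(III)", cr3))
            forms.append(("Cr(VI)", cr6))
        else:
            forms.append((element, conc))

    rows = []
    for scenario in scenarios:
        for form, conc in forms:
            add = average_daily_dose(conc, scenario)
            ladd = lifetime_average_daily_dose(conc, scenario)
            row: dict = {
                "scenario": scenario.label,
                "element_form": form,
                "concentration_mg_kg": conc,
                "add": add,
                "hq": None,
                "hq_zone": None,
                "ladd": ladd,
                "cr": None,
                "cr_zone": None,
                "flag": "",
            }
            entry = tox.get(form)
            if entry is None:
                row["flag"] = "no_toxicity_data"
            else:
                if entry.rfd is not None:
                    hq = hazard_quotient(add, entry)
                    row["hq"] = hq
                    row["hq_zone"] = classify_hq(hq).value
                if entry.sf is not None:
                    cr = carcinogenic_risk(ladd, entry)
                    row["cr"] = cr
                    row["cr_zone"] = classify_cr(cr).value
                if entry.rfd is None or entry.sf is None:
                    missing = "rfd" if entry.rfd is None else "sf"
                    row["flag"] = f"missing_{missing}"
            rows.append(row)
    return pd.DataFrame(rows)
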
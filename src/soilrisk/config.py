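"""YAML configuration round-trip for toxicity constants and scenarios.

Schema version 1:

.. code-block:: yaml

    version: 1
    toxicity:
      As: {rfd: 3.0e-4, sf: 1.5}
      Pb: {sf: 8.5e-3}
    scenarios:
      adult_combined:
        ir: 20.0, ef: 350.0, ed: 75.0, at: 75.0, lt: 75.0, bw: 80.8
"""

from __future__ import annotations

from pathlib import Path

import yaml

from soilrisk.errors import SchemaError
from soilrisk.exposure import ExposureScenario, ToxicityParams
from soilrisk.scenarios import ScenarioTable

SCHEMA_VERSION = 1


def dump_config(
    path,
    toxicity: dict[str, ToxicityParams] | None = None,
    scenarios: ScenarioTable | None = None,
) -> None:
    """Write toxicity constants and/or scenarios to a YAML file."""
    doc: dict = {"version": SCHEMA_VERSION}
    if toxicity is not None:
        doc["toxicity"] = {
            form: {
                k: v
                for k, v in (("rfd", t.rfd), ("sf", t.sf))
                if v is not None
            }
            for form, t in toxicity.items()
        }
    if scenarios is not None:
        doc["scenarios"] = {
            s.label: {
                "ir": s.ir, "ef": s.ef, "ed": s.ed,
                "at": s.at, "lt": s.lt, "bw": s.bw, "cf": s.cf,
            }
            for s in scenarios
        }
    Path(path).write_text(yaml.safe_dump(doc, sort_keys=False))


def load_config(path) -> dict:
    """Load a config file into ``{"toxicity": ..., "scenarios": ...}``.

    ``toxicity`` maps element form to :class:`ToxicityParams`;
    ``scenarios`` is a :class:`ScenarioTable`. Either may be absent.
    """
    doc = yaml.safe_load(Path(path).read_text())
    if not isinstance(doc, dict) or doc.get("version") != SCHEMA_VERSION:
        raise SchemaError(
            f"config {path} missing/unsupported schema version "
            f"(expected {SCHEMA_VERSION})"
        )
    out: dict = {}
    if "toxicity" in doc:
        out["toxicity"] = {
            form: ToxicityParams(element_form=form, **entry)
            for form, entry in doc["toxicity"].items()
        }
    if "scenarios" in doc:
        table = ScenarioTable()
        for label, entry in doc["scenarios"].items():
            table.add(ExposureScenario(label=label, **entry), provenance=str(path))
        out["scenarios"] = table
    return out
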
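"""File round-tripping: contact CSVs, layer/reach/run reports.

CSV dialect is fixed (UTF-8, comma separator, '.' decimal, mandatory
header row); malformed contact rows are reported with their line
numbers.
"""

from __future__ import annotations

import json
from pathlib import Path
import pandas as pd

from .lattice_sim import EnsembleResult
from .layer_detect import ContactTable, LayerFit
from .reach import ReachCurve

__all__ = ["load_contacts", "write_report", "contacts_to_csv"]

_REQUIRED_COLUMNS = ("ego_id", "alter_id", "contact_rate_per_day")


class ContactFileError(ValueError):
    """Raised for malformed contact CSV inputs."""


def load_contacts(path: str | Path, ego_id: str | None = None) -> ContactTable:
    """Read a contact table from ``contacts.csv``.

    The file must have header ``ego_id,alter_id,contact_rate_per_day``.
    If the file holds several egos, ``ego_id`` selects one; otherwise it
    must hold exactly one.  Malformed rows raise with their line number
    (header = line 1).
    """
    path = Path(path)
    try:
        df = pd.read_csv(path, dtype={"ego_id": str, "alter_id": str})
    except pd.errors.EmptyDataError:
        raise ContactFileError(f"{path}: file is empty") from None
    missing = [c for c in _REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise ContactFileError(f"{path}: missing required column(s) {', '.join(missing)}")
    if len(df) == 0:
        raise ContactFileError(f"{path}: no contact rows")
    rates = pd.to_numeric(df["contact_rate_per_day"], errors="coerce")
    bad = df.index[rates.isna() | (rates <= 0)]
    if len(bad) > 0:
        lines = ", ".join(str(i + 2) for i in bad[:5])  # +2: header + 0-base
        raise ContactFileError(
            f"{path}: non-numeric or non-positive contact_rate_per_day at line(s) {lines}"
        )
    df = df.assign(contact_rate_per_day=rates)
    egos = df["ego_id"].unique()
    if ego_id is not None:
        df = df[df["ego_id"] == ego_id]
        if len(df) == 0:
            raise ContactFileError(f"{path}: no rows for ego {ego_id!r}")
    elif len(egos) > 1:
        raise ContactFileError(
            f"{path}: {len(egos)} egos present; select one with ego_id="
        )
    return ContactTable(
        alter_ids=tuple(df["alter_id"]),
        contact_rates=tuple(df["contact_rate_per_day"]),
    )


def contacts_to_csv(table: ContactTable, path: str | Path, ego_id: str = "ego_1") -> None:
    """Write a contact table in the canonical CSV layout."""
    pd.DataFrame(
        {
            "ego_id": ego_id,
            "alter_id": table.alter_ids,
            "contact_rate_per_day": table.contact_rates,
        }
    ).to_csv(path, index=False)


def write_report(results, path: str | Path, format: str | None = None) -> None:
    """Serialize a result object to JSON or CSV.

    ``LayerFit`` and plain dicts go to JSON; ``ReachCurve`` and
    ``EnsembleResult`` go to CSV with a header row.  The format is
    inferred from the suffix when not given; round-tripping reproduces
    values to double precision.
    """
    path = Path(path)
    if format is None:
        format = path.suffix.lstrip(".").lower() or "json"
    if format not in ("json", "csv"):
        raise ValueError(f"unsupported report format {format!r}")

    if isinstance(results, ReachCurve):
        if format == "json":
            payload = {
                "community_sizes": list(results.community_sizes),
                "values": list(results.values),
            }
            path.write_text(json.dumps(payload, indent=2) + "\n")
        else:
            pd.DataFrame(
                {"community_size": results.community_sizes, "reach": results.values}
            ).to_csv(path, index=False)
        return
    if isinstance(results, EnsembleResult):
        rows = [
            {
                "rep": i,
                "outcome": r.outcome,
                "generations": r.generations,
                "final_mutants": r.final_mutants,
            }
            for i, r in enumerate(results.results)
        ]
        if format == "csv":
            pd.DataFrame(rows).to_csv(path, index=False)
        else:
            summary = {
                "n_reps": results.n_reps,
                "extinction_fraction": results.extinction_fraction,
                "penetrant_fraction": results.penetrant_fraction,
                "censored_fraction": results.censored_fraction,
                "penetrance_time_quantiles": results.penetrance_time_quantiles,
                "runs": rows,
            }
            path.write_text(json.dumps(summary, indent=2) + "\n")
        return
    if isinstance(results, LayerFit):
        results = results.to_dict()
    if format == "json":
        path.write_text(json.dumps(results, indent=2) + "\n")
    else:
        pd.DataFrame(results).to_csv(path, index=False)
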
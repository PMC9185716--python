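"""Record-level quality control for online survey cohorts.

Online surveys recruited through social media attract large numbers of
ineligible, duplicate, and outright fraudulent (bot) responses; in published
validations of this kind roughly half of completed surveys are discarded.
This module applies the filtering pipeline in three ordered stages and emits
a stage-by-stage flow report:

1. *Eligibility*: respondents must be 11-21 years old, US resident, have a
   past-year dating relationship, not have completed the survey before, have
   skipped at most 10 questions, and not have timed out.  Each ineligible
   record is labeled with its first failing reason in a fixed order so the
   per-reason counts partition the ineligible total.
2. *Consent*: assent/consent recorded as a flag.
3. *Fraud detection*: five rules — (a) reported zip does not match the
   reported state, (b) all five open-text answers blank or nonsense,
   (c) IP address outside the US, (d) duplicate respondent key, (e) IP
   coordinates far from the reported zip.  A record is removed when any rule
   fires; per-rule counts may overlap.

Zip/state and coordinate checks use an injected lookup table (a miniature
packaged table is provided; supply a complete one for real data).  No network
calls are made.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

ELIGIBILITY_REASONS = (
    "prior_completion",
    "no_dating",
    "age",
    "skipped_gt10",
    "non_us",
    "timed_out",
)

FRAUD_RULES = (
    "zip_state_mismatch",
    "blank_or_nonsense_text",
    "foreign_ip",
    "duplicate",
    "geo_mismatch",
)

AGE_MIN, AGE_MAX = 11, 21
MAX_SKIPPED = 10
#: Maximum plausible distance (km) between an IP geolocation and the centroid
#: of the reported zip before rule (e) fires.  Generous: zip centroids and IP
#: geolocation are both coarse.
GEO_THRESHOLD_KM = 400.0

OPEN_TEXT_COLUMNS = tuple(f"open_text_{i}" for i in range(1, 6))

REQUIRED_COLUMNS = (
    "record_id",
    "age_years",
    "us_resident",
    "dated_past_year",
    "prior_completion",
    "skipped_count",
    "timed_out",
    "consented",
    "zip",
    "state",
    "ip_country",
    "ip_lat",
    "ip_lon",
    "duplicate_key",
    *OPEN_TEXT_COLUMNS,
)

US_STATE_CODES = frozenset(
    """AL AK AZ AR CA CO CT DE DC FL GA HI ID IL IN IA KS KY LA ME MD MA MI MN
    MS MO MT NE NV NH NJ NM NY NC ND OH OK OR PA RI SC SD TN TX UT VT VA WA WV
    WI WY""".split()
)


class RecordValidationError(ValueError):
    """A record is missing required QC metadata (not silently dropped)."""


class ZipLookupError(KeyError):
    """A state code could not be resolved against the zip/state table."""


def load_zip_table(path: str | Path | None = None) -> pd.DataFrame:
    """Load a zip -> (state, lat, lon) lookup table (CSV).

    Defaults to the packaged miniature table (one or more zips per state),
    which is sufficient for tests and synthetic cohorts.
    """
    if path is None:
        ref = resources.files("marsha_screen.data").joinpath("zip_state_mini.csv")
        with ref.open("r", encoding="utf-8") as fh:
            df = pd.read_csv(fh, dtype={"zip": str})
    else:
        df = pd.read_csv(path, dtype={"zip": str})
    missing = {"zip", "state", "lat", "lon"} - set(df.columns)
    if missing:
        raise ValueError(f"zip table missing columns: {sorted(missing)}")
    return df.set_index("zip")


def haversine_km(lat1: float, lon1: float, lat2: float, lon2: float) -> float:
    """Great-circle distance in kilometres."""
    rlat1, rlon1, rlat2, rlon2 = map(math.radians, (lat1, lon1, lat2, lon2))
    dlat, dlon = rlat2 - rlat1, rlon2 - rlon1
    a = math.sin(dlat / 2) ** 2 + math.cos(rlat1) * math.cos(rlat2) * math.sin(dlon / 2) ** 2
    return 2 * 6371.0 * math.asin(math.sqrt(a))


def is_nonsense_text(text: object) -> bool:
    """Heuristic for a blank or bot-like open-text answer.

    Fires when the trimmed text is empty, shorter than 2 characters, contains
    no vowel, or is a single repeated character.  Only the conjunction over
    all five open-text fields counts as a fraud signal.
    """
    if text is None or (isinstance(text, float) and math.isnan(text)):
        return True
    s = str(text).strip()
    if len(s) < 2:
        return True
    low = s.lower()
    if not any(v in low for v in "aeiouy"):
        return True
    if len(set(low)) == 1:
        return True
    return False


def _validate_records(records: pd.DataFrame) -> None:
    missing_cols = [c for c in REQUIRED_COLUMNS if c not in records.columns]
    if missing_cols:
        raise RecordValidationError(f"records missing required columns: {missing_cols}")
    meta = [
        c
        for c in REQUIRED_COLUMNS
        if c not in OPEN_TEXT_COLUMNS  # open text may legitimately be blank
    ]
    null_mask = records[meta].isna().any(axis=1)
    if null_mask.any():
        bad = records.loc[null_mask, "record_id"].tolist()[:5]
        raise RecordValidationError(
            f"{int(null_mask.sum())} record(s) with missing QC metadata, e.g. {bad}"
        )


def eligibility_filter(
    records: pd.DataFrame,
) -> tuple[pd.DataFrame, pd.Series, dict[str, int]]:
    """Split records into eligible and ineligible with per-reason counts.

    Returns ``(eligible_records, reason_by_record, reason_counts)``.  Each
    ineligible record carries exactly one primary reason: the first failing
    rule in the fixed order ``ELIGIBILITY_REASONS``.
    """
    _validate_records(records)
    checks = {
        "prior_completion": records["prior_completion"].astype(bool),
        "no_dating": ~records["dated_past_year"].astype(bool),
        "age": ~records["age_years"].astype(int).between(AGE_MIN, AGE_MAX),
        "skipped_gt10": records["skipped_count"].astype(int) > MAX_SKIPPED,
        "non_us": ~records["us_resident"].astype(bool),
        "timed_out": records["timed_out"].astype(bool),
    }
    reason = pd.Series(pd.NA, index=records.index, dtype="object")
    for name in ELIGIBILITY_REASONS:
        reason = reason.where(reason.notna() | ~checks[name], name)
    counts = {name: int((reason == name).sum()) for name in ELIGIBILITY_REASONS}
    return records.loc[reason.isna()], reason, counts


def fraud_flags(
    record: pd.Series,
    zip_table: pd.DataFrame,
    duplicate_key_counts: pd.Series | None = None,
    geo_threshold_km: float = GEO_THRESHOLD_KM,
    rules: Iterable[str] = FRAUD_RULES,
) -> set[str]:
    """Fraud-rule labels triggered by one record; fraudulent iff nonempty.

    ``duplicate_key_counts`` is the cohort-level value_counts of the
    duplicate key (the rule needs cohort context); omit it to skip the
    duplicate rule.  An unknown reported zip counts as a zip/state mismatch
    (an unverifiable zip is exactly what rule (a) targets); an unknown state
    code raises :class:`ZipLookupError` because it indicates malformed input
    rather than fraud.
    """
    rules = set(rules)
    flags: set[str] = set()
    state = str(record["state"]).strip().upper()
    if state not in US_STATE_CODES:
        raise ZipLookupError(
            f"record {record.get('record_id', '?')}: unknown state code {state!r}"
        )
    zip_code = str(record["zip"]).strip()
    zip_row = zip_table.loc[zip_code] if zip_code in zip_table.index else None

    if "zip_state_mismatch" in rules:
        if zip_row is None or str(zip_row["state"]).upper() != state:
            flags.add("zip_state_mismatch")
    if "blank_or_nonsense_text" in rules:
        if all(is_nonsense_text(record[c]) for c in OPEN_TEXT_COLUMNS):
            flags.add("blank_or_nonsense_text")
    if "foreign_ip" in rules:
        if str(record["ip_country"]).strip().upper() != "US":
            flags.add("foreign_ip")
    if "duplicate" in rules and duplicate_key_counts is not None:
        if duplicate_key_counts.get(record["duplicate_key"], 0) > 1:
            flags.add("duplicate")
    if "geo_mismatch" in rules and zip_row is not None:
        d = haversine_km(
            float(record["ip_lat"]), float(record["ip_lon"]),
            float(zip_row["lat"]), float(zip_row["lon"]),
        )
        if d > geo_threshold_km:
            flags.add("geo_mismatch")
    return flags


@dataclass
class FlowReport:
    """Counts at each filtering stage; a telescoping partition of the input."""

    screened: int = 0
    ineligible: dict[str, int] = field(default_factory=dict)
    eligible: int = 0
    non_consent: int = 0
    consented: int = 0
    fraud_by_rule: dict[str, int] = field(default_factory=dict)
    fraud_flagged: int = 0
    final: int = 0

    @property
    def ineligible_total(self) -> int:
        return sum(self.ineligible.values())

    def validate(self) -> None:
        assert self.eligible == self.screened - self.ineligible_total
        assert self.consented == self.eligible - self.non_consent
        assert self.final == self.consented - self.fraud_flagged

    def to_dict(self) -> dict:
        return {
            "screened": self.screened,
            "ineligible_total": self.ineligible_total,
            "ineligible": dict(self.ineligible),
            "eligible": self.eligible,
            "non_consent": self.non_consent,
            "consented": self.consented,
            "fraud_flagged": self.fraud_flagged,
            "fraud_by_rule": dict(self.fraud_by_rule),
            "final": self.final,
        }

    def to_json(self, **kwargs) -> str:
        return json.dumps(self.to_dict(), indent=2, **kwargs)

    def to_text(self) -> str:
        lines = [f"screened                {self.screened}"]
        for r in ELIGIBILITY_REASONS:
            lines.append(f"  ineligible/{r:<18}{self.ineligible.get(r, 0)}")
        lines.append(f"eligible                {self.eligible}")
        lines.append(f"  non-consent           {self.non_consent}")
        lines.append(f"consented               {self.consented}")
        for r in FRAUD_RULES:
            lines.append(f"  fraud/{r:<24}{self.fraud_by_rule.get(r, 0)}")
        lines.append(f"fraud-flagged (any)     {self.fraud_flagged}")
        lines.append(f"final analytic sample   {self.final}")
        return "\n".join(lines)


def run_flow(
    records: pd.DataFrame,
    zip_table: pd.DataFrame | None = None,
    fraud_rules: Sequence[str] = FRAUD_RULES,
    geo_threshold_km: float = GEO_THRESHOLD_KM,
) -> tuple[pd.DataFrame, FlowReport]:
    """Run eligibility -> consent -> fraud filtering and report stage counts.

    Returns the analytic records and a :class:`FlowReport`.  Empty input
    yields an all-zero report.  The pipeline is idempotent: rerunning it on
    its own output removes nothing.
    """
    report = FlowReport(screened=len(records))
    report.ineligible = {r: 0 for r in ELIGIBILITY_REASONS}
    report.fraud_by_rule = {r: 0 for r in fraud_rules}
    if records.empty:
        return records.copy(), report
    if zip_table is None:
        zip_table = load_zip_table()

    eligible, _, report.ineligible = eligibility_filter(records)
    report.eligible = len(eligible)

    consented = eligible.loc[eligible["consented"].astype(bool)]
    report.consented = len(consented)
    report.non_consent = report.eligible - report.consented

    dup_counts = consented["duplicate_key"].value_counts()
    flagged = np.zeros(len(consented), dtype=bool)
    for i, (_, rec) in enumerate(consented.iterrows()):
        labels = fraud_flags(
            rec,
            zip_table,
            duplicate_key_counts=dup_counts,
            geo_threshold_km=geo_threshold_km,
            rules=fraud_rules,
        )
        for lab in labels:
            report.fraud_by_rule[lab] += 1
        flagged[i] = bool(labels)
    report.fraud_flagged = int(flagged.sum())
    analytic = consented.loc[~flagged]
    report.final = len(analytic)
    report.validate()
    return analytic, report
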
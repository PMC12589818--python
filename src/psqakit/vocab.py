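"""Controlled vocabularies and disease-site normalization.

Multi-facility QA databases only stay comparable if categorical fields come
from shared vocabularies.  This module ships editable default tables for
facilities, treatment machines and QA devices (modelled on a four-hospital
university group running Varian/Elekta/Accuray linacs with ArcCHECK, Delta4
and ionization-chamber measurement devices) plus a synonym map that collapses
free-text disease labels onto five canonical site categories.

All tables are plain data; callers may pass their own replacements to the
validation and normalization functions.
"""

from __future__ import annotations

# Canonical disease-site categories.  Site is a mandatory stratification
# field: every analysis (limits, charts, alerts) is grouped by it.
SITES: tuple[str, ...] = ("CNS", "HeadNeck", "Chest", "Pelvis", "Other")

#: Sentinel returned by :func:`normalize_site` when a label cannot be mapped.
#: It is a value, not an error — ingest policy decides what to do with it.
UNMAPPED = "UNMAPPED"

# Default facility labels (a four-hospital group).
FACILITIES: tuple[str, ...] = (
    "UniversityHospital",
    "KotoToyosu",
    "NorthernYokohama",
    "Fujigaoka",
)

# Treatment machines per facility.
MACHINES: dict[str, tuple[str, ...]] = {
    "UniversityHospital": ("Clinac iX", "Radixact"),
    "KotoToyosu": ("Infinity",),
    "NorthernYokohama": ("TrueBeam STx",),
    "Fujigaoka": ("TrueBeam",),
}

# QA measurement devices per facility.
QA_DEVICES: dict[str, tuple[str, ...]] = {
    "UniversityHospital": ("ArcCHECK", "Delta4", "Farmer Chamber", "A1SL Chamber"),
    "KotoToyosu": ("ArcCHECK", "Farmer Chamber"),
    "NorthernYokohama": ("Delta4", "Pinpoint Chamber"),
    "Fujigaoka": ("ArcCHECK", "Farmer Chamber"),
}

# Synonym map: lower-cased, whitespace-collapsed label -> canonical site.
# Editable/overridable; entries cover the clinical shorthand seen on QA
# verification sheets.  "prostate" maps to Pelvis, "brain" to CNS, etc.
SITE_SYNONYMS: dict[str, str] = {
    # CNS
    "cns": "CNS",
    "central nervous system": "CNS",
    "brain": "CNS",
    "brain mets": "CNS",
    "glioma": "CNS",
    "spine": "CNS",
    "spinal": "CNS",
    # Head & Neck
    "headneck": "HeadNeck",
    "head and neck": "HeadNeck",
    "head & neck": "HeadNeck",
    "head neck": "HeadNeck",
    "h&n": "HeadNeck",
    "hn": "HeadNeck",
    "neck": "HeadNeck",
    "oropharynx": "HeadNeck",
    "nasopharynx": "HeadNeck",
    "larynx": "HeadNeck",
    # Chest
    "chest": "Chest",
    "thorax": "Chest",
    "lung": "Chest",
    "esophagus": "Chest",
    "oesophagus": "Chest",
    "breast": "Chest",
    # Pelvis
    "pelvis": "Pelvis",
    "prostate": "Pelvis",
    "cervix": "Pelvis",
    "uterus": "Pelvis",
    "rectum": "Pelvis",
    "bladder": "Pelvis",
    "gynecologic": "Pelvis",
    # Other
    "other": "Other",
    "others": "Other",
    "abdomen": "Other",
    "liver": "Other",
    "pancreas": "Other",
    "whole body": "Other",
}


def normalize_site(raw_label: str | None, synonyms: dict[str, str] | None = None) -> str:
    """Map a free-text disease label onto one of the five site categories.

    Case and surrounding/internal whitespace are ignored; known synonyms
    (e.g. ``"prostate"`` -> ``"Pelvis"``) are resolved through the synonym
    table.  Labels that cannot be mapped return :data:`UNMAPPED` — never a
    guess.  Idempotent: canonical labels map to themselves.

    Parameters
    ----------
    raw_label
        The label as entered; ``None`` or blank returns :data:`UNMAPPED`.
    synonyms
        Optional replacement synonym table (lower-case key -> canonical site).
    """
    if raw_label is None:
        return UNMAPPED
    table = SITE_SYNONYMS if synonyms is None else synonyms
    key = " ".join(str(raw_label).split()).lower()
    if not key:
        return UNMAPPED
    # canonical labels (and UNMAPPED itself) are fixed points
    for site in SITES:
        if key == site.lower():
            return site
    if key == UNMAPPED.lower():
        return UNMAPPED
    return table.get(key, UNMAPPED)


def known_facilities() -> tuple[str, ...]:
    return FACILITIES


def known_machines() -> tuple[str, ...]:
    return tuple(m for ms in MACHINES.values() for m in ms)


def known_devices() -> tuple[str, ...]:
    return tuple(d for ds in QA_DEVICES.values() for d in ds)
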
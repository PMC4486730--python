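"""Tab-delimited readers/writers for morphometric and scintillation tables.

Schemas follow the deposited-field-data convention: one row per animal x
replicate x site for morphometrics; one row per sample x replicate for
counts.  A :class:`SchemaConfig` absorbs alternative column headers,
site-name aliases, and a cm/mm toggle for depth units.  Readers reject
malformed rows with errors naming the row and column rather than
silently coercing.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from .dilution import DilutionRecord, StandardDilution
from .geometry import N_SITES, SITES, MorphometricProfile

__all__ = [
    "SchemaConfig",
    "SchemaError",
    "read_morphometrics",
    "write_morphometrics",
    "read_counts",
    "write_counts",
    "MORPH_COLUMNS",
    "COUNT_COLUMNS",
]

MORPH_COLUMNS = ("animal_id", "replicate", "site", "girth_cm", "height_cm",
                 "width_cm", "curvilinear_cm", "us_dorsal_cm", "us_lateral_cm",
                 "total_length_cm", "mass_kg")

COUNT_COLUMNS = ("animal_id", "sample_id", "replicate", "role", "cpm_per_ml",
                 "aliquot_ml", "diluent_ml", "injected_g", "mass_kg")

#: Roles a count row may carry.
COUNT_ROLES = ("background", "equilibrium", "standard")


class SchemaError(ValueError):
    """A required column is missing or a cell cannot be interpreted."""


@dataclass
class SchemaConfig:
    """Column-name remapping and unit declarations for the readers.

    ``columns`` maps logical names (the defaults above) to the file's
    actual headers.  ``depth_unit`` may be 'cm' or 'mm' (ultrasound
    depths are converted to cm on read).  ``site_aliases`` maps file
    site spellings to the canonical site names.
    """

    columns: dict = field(default_factory=dict)
    depth_unit: str = "cm"
    site_aliases: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.depth_unit not in ("cm", "mm"):
            raise ValueError("depth_unit must be 'cm' or 'mm'")

    @classmethod
    def from_yaml(cls, path) -> "SchemaConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls(columns=raw.get("columns", {}),
                   depth_unit=raw.get("depth_unit", "cm"),
                   site_aliases=raw.get("site_aliases", {}))

    def resolve(self, logical: str) -> str:
        return self.columns.get(logical, logical)

    def canonical_site(self, name: str) -> str:
        name = self.site_aliases.get(str(name), str(name)).strip().lower()
        if name not in SITES:
            raise SchemaError(f"unknown site {name!r}; expected one of {SITES}")
        return name

    @property
    def depth_factor(self) -> float:
        return 0.1 if self.depth_unit == "mm" else 1.0


def _require_columns(frame: pd.DataFrame, schema: SchemaConfig, logical_names):
    missing = [schema.resolve(c) for c in logical_names
               if schema.resolve(c) not in frame.columns]
    if missing:
        raise SchemaError(f"missing required column(s): {', '.join(missing)}")


def _numeric(frame: pd.DataFrame, schema: SchemaConfig, logical: str,
             allow_nan: bool = False) -> pd.Series:
    col = schema.resolve(logical)
    out = pd.to_numeric(frame[col], errors="coerce")
    bad = out.isna() & frame[col].notna() if allow_nan else out.isna()
    if bad.any():
        row = int(frame.index[bad][0])
        raise SchemaError(f"non-numeric value in column {col!r} at row {row}")
    return out


def read_morphometrics(path, schema: SchemaConfig | None = None
                       ) -> list[MorphometricProfile]:
    """Read a tab-delimited morphometric table into per-animal profiles."""
    schema = schema or SchemaConfig()
    frame = pd.read_csv(path, sep="\t")
    _require_columns(frame, schema, ("animal_id", "replicate", "site",
                                     "girth_cm", "curvilinear_cm",
                                     "total_length_cm", "mass_kg"))
    profiles = []
    for animal, grp in frame.groupby(schema.resolve("animal_id"), sort=False):
        grp = grp.reset_index(drop=True)
        reps = sorted(grp[schema.resolve("replicate")].unique())
        n_rep = len(reps)
        arrays = {k: np.full((n_rep, N_SITES), np.nan) for k in
                  ("girth", "height", "width", "curvilinear",
                   "us_dorsal", "us_lateral")}
        have = {k: schema.resolve(f"{k}_cm") in grp.columns
                for k in arrays}
        numeric = {}
        for k in arrays:
            if have[k]:
                numeric[k] = _numeric(grp, schema, f"{k}_cm",
                                      allow_nan=k.startswith("us_"))
        total_len = np.full(n_rep, np.nan)
        rep_index = {r: i for i, r in enumerate(reps)}
        for i in range(len(grp)):
            r = rep_index[grp.loc[i, schema.resolve("replicate")]]
            s_name = schema.canonical_site(grp.loc[i, schema.resolve("site")])
            s = SITES.index(s_name)
            for k in arrays:
                if have[k]:
                    val = numeric[k].iloc[i]
                    if k.startswith("us_") and not pd.isna(val):
                        val = val * schema.depth_factor
                    arrays[k][r, s] = val
        tl = _numeric(grp, schema, "total_length_cm")
        for i in range(len(grp)):
            r = rep_index[grp.loc[i, schema.resolve("replicate")]]
            total_len[r] = tl.iloc[i]
        mass = float(_numeric(grp, schema, "mass_kg").iloc[0])
        for k in ("girth", "curvilinear"):
            if np.any(np.isnan(arrays[k])):
                raise SchemaError(
                    f"animal {animal!r}: incomplete {k} measurements "
                    "(every replicate needs all 8 sites)")
        profiles.append(MorphometricProfile(
            animal_id=str(animal),
            girth=arrays["girth"],
            height=arrays["height"] if have["height"] else np.full((n_rep, N_SITES), np.nan),
            width=arrays["width"] if have["width"] else np.full((n_rep, N_SITES), np.nan),
            curvilinear=arrays["curvilinear"],
            total_length=total_len,
            mass=mass,
            us_dorsal=arrays["us_dorsal"] if have["us_dorsal"] else None,
            us_lateral=arrays["us_lateral"] if have["us_lateral"] else None,
        ))
    return profiles


def write_morphometrics(profiles, path):
    """Write profiles to the default tab-delimited schema."""
    rows = []
    for p in profiles:
        for r in range(p.n_replicates):
            for s, site in enumerate(SITES):
                rows.append({
                    "animal_id": p.animal_id,
                    "replicate": r,
                    "site": site,
                    "girth_cm": p.girth[r, s],
                    "height_cm": p.height[r, s],
                    "width_cm": p.width[r, s],
                    "curvilinear_cm": p.curvilinear[r, s],
                    "us_dorsal_cm": p.us_dorsal[r, s] if p.us_dorsal is not None else np.nan,
                    "us_lateral_cm": p.us_lateral[r, s] if p.us_lateral is not None else np.nan,
                    "total_length_cm": p.total_length[r],
                    "mass_kg": p.mass,
                })
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_counts(path, schema: SchemaConfig | None = None) -> dict:
    """Read a scintillation-count table.

    Returns ``{"standards": [StandardDilution...],
    "records": [DilutionRecord...]}``.  Standard rows need aliquot and
    diluent volumes; equilibrium/background rows need the per-mL count;
    animal rows need the injected mass and animal mass.  The stock
    specific activity for the records is computed from the standards in
    the same file.
    """
    from .dilution import stock_specific_activity

    schema = schema or SchemaConfig()
    frame = pd.read_csv(path, sep="\t")
    _require_columns(frame, schema, ("animal_id", "role", "cpm_per_ml"))
    role_col = schema.resolve("role")
    bad_role = ~frame[role_col].isin(COUNT_ROLES)
    if bad_role.any():
        row = int(frame.index[bad_role][0])
        raise SchemaError(f"unknown role at row {row}: {frame.loc[row, role_col]!r}")
    cpm = _numeric(frame, schema, "cpm_per_ml")
    if (cpm < 0).any():
        row = int(frame.index[cpm < 0][0])
        raise SchemaError(f"negative CPM at row {row}")

    standards = []
    std = frame[frame[role_col] == "standard"]
    if len(std):
        _require_columns(std, schema, ("aliquot_ml", "diluent_ml"))
        for _sid, grp in std.groupby(schema.resolve("sample_id"), sort=False):
            standards.append(StandardDilution(
                aliquot_ml=float(_numeric(grp, schema, "aliquot_ml").iloc[0]),
                diluent_ml=float(_numeric(grp, schema, "diluent_ml").iloc[0]),
                activities_cpm_ml=_numeric(grp, schema, "cpm_per_ml").to_numpy(),
            ))
    records = []
    animals = frame[frame[role_col].isin(("background", "equilibrium"))]
    if len(animals):
        if not standards:
            raise SchemaError("animal count rows present but no standards to "
                              "compute the stock specific activity")
        stock = stock_specific_activity(standards)
        _require_columns(animals, schema, ("injected_g", "mass_kg"))
        for animal, grp in animals.groupby(schema.resolve("animal_id"), sort=False):
            eq = grp[grp[role_col] == "equilibrium"]
            bg = grp[grp[role_col] == "background"]
            if not len(eq) or not len(bg):
                raise SchemaError(
                    f"animal {animal!r} needs both equilibrium and background rows")
            records.append(DilutionRecord(
                animal_id=str(animal),
                injected_g=float(_numeric(eq, schema, "injected_g").iloc[0]),
                stock_cpm_ml=stock,
                eq_cpm_ml=_numeric(eq, schema, "cpm_per_ml").to_numpy(),
                bg_cpm_ml=_numeric(bg, schema, "cpm_per_ml").to_numpy(),
                mass_kg=float(_numeric(eq, schema, "mass_kg").iloc[0]),
            ))
    return {"standards": standards, "records": records}


def write_counts(standards, records, path):
    """Write standards and dilution records to the default count schema."""
    rows = []
    for i, s in enumerate(standards):
        for r, act in enumerate(s.activities_cpm_ml):
            rows.append({"animal_id": "", "sample_id": f"std{i}", "replicate": r,
                         "role": "standard", "cpm_per_ml": act,
                         "aliquot_ml": s.aliquot_ml, "diluent_ml": s.diluent_ml,
                         "injected_g": np.nan, "mass_kg": np.nan})
    for rec in records:
        for role, arr in (("equilibrium", rec.eq_cpm_ml), ("background", rec.bg_cpm_ml)):
            for r, val in enumerate(arr):
                rows.append({"animal_id": rec.animal_id, "sample_id": role,
                             "replicate": r, "role": role, "cpm_per_ml": val,
                             "aliquot_ml": np.nan, "diluent_ml": np.nan,
                             "injected_g": rec.injected_g, "mass_kg": rec.mass_kg})
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
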
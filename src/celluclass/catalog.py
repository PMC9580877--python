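"""Role vocabularies mapping CAZy module families to functional roles.

Every downstream rule — gene typing, genome classification, co-occurrence
focal sets — is driven by a :class:`ModuleCatalog` that assigns CAZy families
to roles: exoglucanase GH, endoglucanase GH, xylanase GH, LPMO (lytic
polysaccharide monooxygenase), cellulose-binding CBM (cCBM), and the three
structural cellulosome/anchoring modules (SLH, cohesin, dockerin).  The
derived role ``cgh`` (cellulolytic GH) is the union of the exoglucanase,
endoglucanase and LPMO sets.

The shipped default catalog is implementer-curated from CAZy activity
documentation and is fully overridable from a YAML or TSV file, so the
classification engine never depends on one particular vocabulary.
"""

from __future__ import annotations

import hashlib
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from celluclass.errors import ConfigurationError

STRUCTURAL_ROLES = ("slh", "cohesin", "dockerin")

# Accepted spellings for the structural modules, lower-cased.
_STRUCTURAL_ALIASES = {
    "slh": "SLH",
    "cohesin": "cohesin",
    "cohesion": "cohesin",
    "coh": "cohesin",
    "dockerin": "dockerin",
    "doc": "dockerin",
    "dockerin_1": "dockerin",
}

_ROLE_KEYS = ("exo_gh", "endo_gh", "xylanase_gh", "lpmo", "ccbm")

# Curated default role sets.  Families explicitly tied to a role in the
# cellulolysis literature; GH9 and GH5 are promiscuous (predominantly
# endoglucanase, occasionally exoglucanase) and GH9 is deliberately listed
# under both roles.
DEFAULT_CATALOG_CONFIG: dict[str, list[str]] = {
    # chain-end processive cellobiohydrolases
    "exo_gh": ["GH48", "GH6", "GH7", "GH9"],
    # internal amorphous-site endoglucanases
    "endo_gh": ["GH5", "GH8", "GH9", "GH12", "GH44", "GH45", "GH74"],
    # hemicellulose backbone hydrolases
    "xylanase_gh": ["GH10", "GH11", "GH30", "GH43", "GH51", "GH98", "GH120"],
    # oxidative 1,4-glycosidic bond cleavage
    "lpmo": ["AA9", "AA10", "AA11"],
    # cellulose-binding CBMs
    "ccbm": [
        "CBM1", "CBM2", "CBM3", "CBM4", "CBM6", "CBM8", "CBM9", "CBM10",
        "CBM28", "CBM30", "CBM44", "CBM46", "CBM49", "CBM63", "CBM64",
    ],
}


def normalize_family(label: str) -> str:
    """Normalize a raw HMM/family label to its catalog form.

    Strips a trailing ``.hmm`` suffix and canonicalizes structural-module
    spellings (``cohesion`` -> ``cohesin``, ``DOC`` -> ``dockerin``, any case
    of ``slh`` -> ``SLH``).  Case of CAZy family labels is preserved.
    """
    label = label.strip()
    if label.lower().endswith(".hmm"):
        label = label[:-4]
    canon = _STRUCTURAL_ALIASES.get(label.lower())
    if canon is not None:
        return canon
    return label


def parent_family(label: str) -> str:
    """Collapse a subfamily label (``GH5_4``) to its parent family (``GH5``).

    Role catalogs are defined at family level; reports keep the full label.
    """
    label = normalize_family(label)
    if "_" in label:
        head = label.split("_", 1)[0]
        # only collapse CAZy-style FAMILYNUMBER_SUB labels
        if head and head[-1].isdigit():
            return head
    return label


@dataclass(frozen=True)
class ModuleCatalog:
    """Immutable role vocabulary driving gene typing and classification."""

    exo_gh: frozenset[str]
    endo_gh: frozenset[str]
    xylanase_gh: frozenset[str]
    lpmo: frozenset[str]
    ccbm: frozenset[str]
    structural: frozenset[str] = field(default=frozenset({"SLH", "cohesin", "dockerin"}))

    @property
    def cgh(self) -> frozenset[str]:
        """Families counted as cellulolytic GH: exo/endoglucanase or LPMO."""
        return self.exo_gh | self.endo_gh | self.lpmo

    def focal_modules(self) -> list[str]:
        """The default co-occurrence focal list: exo + endo + xylanase GH
        modules plus the three structural modules (LPMOs excluded)."""
        gh = sorted(self.exo_gh | self.endo_gh | self.xylanase_gh, key=_family_sort_key)
        return gh + ["cohesin", "dockerin", "SLH"]

    def to_config(self) -> dict[str, list[str]]:
        return {
            "exo_gh": sorted(self.exo_gh, key=_family_sort_key),
            "endo_gh": sorted(self.endo_gh, key=_family_sort_key),
            "xylanase_gh": sorted(self.xylanase_gh, key=_family_sort_key),
            "lpmo": sorted(self.lpmo, key=_family_sort_key),
            "ccbm": sorted(self.ccbm, key=_family_sort_key),
        }

    def checksum(self) -> str:
        """Stable digest of the vocabulary, logged so group labels are
        traceable to the catalog that produced them."""
        payload = yaml.safe_dump(self.to_config(), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:12]

    def save(self, path: str | Path) -> Path:
        path = Path(path)
        path.write_text(yaml.safe_dump(self.to_config(), sort_keys=True))
        return path


def _family_sort_key(label: str):
    head = "".join(c for c in label if not c.isdigit() and c != "_")
    digits = "".join(c if c.isdigit() else " " for c in label).split()
    return (head, [int(d) for d in digits])


def _read_config(path: Path) -> dict[str, list[str]]:
    text = path.read_text()
    if path.suffix.lower() in {".yaml", ".yml", ".json"}:
        data = yaml.safe_load(text)
        if not isinstance(data, dict):
            raise ConfigurationError(f"catalog file {path} must map roles to family lists")
        return {k: list(v) if v else [] for k, v in data.items()}
    # TSV: role <tab> family per line, or role <tab> comma-joined families
    config: dict[str, list[str]] = {}
    for line in text.splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split("\t")
        if len(parts) < 2:
            raise ConfigurationError(f"catalog TSV line {line!r} needs role<TAB>family")
        role = parts[0].strip()
        for cell in parts[1:]:
            config.setdefault(role, []).extend(f.strip() for f in cell.split(",") if f.strip())
    return config


def load_catalog(config: str | Path | dict[str, list[str]] | None = None) -> ModuleCatalog:
    """Build a validated :class:`ModuleCatalog`.

    ``config`` may be ``None`` (shipped default), a mapping of role key to
    family list, or a path to a YAML/TSV file with the same structure.
    Unknown role keys are rejected; duplicate families within one role are
    deduplicated with a warning; an empty exoglucanase or endoglucanase set
    is a configuration error because the genome classifier needs both roles.
    """
    if config is None:
        raw = DEFAULT_CATALOG_CONFIG
    elif isinstance(config, (str, Path)):
        raw = _read_config(Path(config))
    else:
        raw = config

    unknown = set(raw) - set(_ROLE_KEYS) - {"structural"}
    if unknown:
        raise ConfigurationError(f"unknown catalog role keys: {sorted(unknown)}; expected {_ROLE_KEYS}")

    sets: dict[str, frozenset[str]] = {}
    for role in _ROLE_KEYS:
        families = [normalize_family(f) for f in raw.get(role, [])]
        if len(families) != len(set(families)):
            dupes = sorted({f for f in families if families.count(f) > 1})
            warnings.warn(f"catalog role {role!r} lists duplicate families {dupes}; deduplicated")
        sets[role] = frozenset(families)

    if not sets["exo_gh"]:
        raise ConfigurationError("catalog defines no exoglucanase GH families (role exo_gh)")
    if not sets["endo_gh"]:
        raise ConfigurationError("catalog defines no endoglucanase GH families (role endo_gh)")

    catalog = ModuleCatalog(
        exo_gh=sets["exo_gh"],
        endo_gh=sets["endo_gh"],
        xylanase_gh=sets["xylanase_gh"],
        lpmo=sets["lpmo"],
        ccbm=sets["ccbm"],
    )
    if not catalog.cgh:
        raise ConfigurationError("catalog yields an empty cGH set (exo_gh | endo_gh | lpmo)")
    return catalog


def roles_of(family: str, catalog: ModuleCatalog) -> frozenset[str]:
    """Pure role lookup for one family label.

    Subfamily labels are collapsed to their parent family before lookup.
    The derived role ``cgh`` is present whenever ``exo``, ``endo`` or
    ``lpmo`` is.  Unknown families map to the empty set.
    """
    fam = parent_family(family)
    roles: set[str] = set()
    if fam == "SLH":
        roles.add("slh")
    elif fam == "cohesin":
        roles.add("cohesin")
    elif fam == "dockerin":
        roles.add("dockerin")
    if fam in catalog.exo_gh:
        roles.add("exo")
    if fam in catalog.endo_gh:
        roles.add("endo")
    if fam in catalog.xylanase_gh:
        roles.add("xylanase")
    if fam in catalog.lpmo:
        roles.add("lpmo")
    if fam in catalog.ccbm:
        roles.add("ccbm")
    if roles & {"exo", "endo", "lpmo"}:
        roles.add("cgh")
    return frozenset(roles)
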
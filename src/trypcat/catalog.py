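"""Machine-readable rulebook for the six neuro-active tryptophan catabolism pathways.

The package predicts bacterial production potential for six tryptophan-derived
neuro-active metabolites (the "TRYP-6" set): kynurenine, quinolinate, indole,
indole acetic acid (IAA), indole propionic acid (IPA), and tryptamine.  Each
pathway is declared as a :class:`PathwayRule` — an AND/OR tree over enzyme
evidence leaves, optionally tightened by a gene-cluster (operon-proximity)
requirement — and the three tryptophan importers TnaB, AroP and Mtr are
declared as :class:`TransporterSpec` entries.

Evidence comes in two kinds:

``domain``
    presence of a Pfam functional domain on some protein of the genome
    (e.g. the tryptophan 2,3-dioxygenase domain Trp_dioxygenase, PF03301,
    is by itself diagnostic of the kynurenine route);
``homolog``
    a BLAST hit against a curated query protein passing identity / coverage /
    e-value thresholds (used where the catalytic domain is too generic, e.g.
    tryptophanase's Beta_elim_lyase domain).

The shipped default catalog can be dumped to YAML, edited, and reloaded;
fields not overridden in a config file inherit from the default.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Union

import yaml

from .errors import CatalogConfigError, CatalogValidationError

#: Canonical column/row order for the six metabolites, used everywhere downstream.
METABOLITES = ("kynurenine", "quinolinate", "indole", "IAA", "IPA", "tryptamine")

TRANSPORTERS = ("TnaB", "AroP", "Mtr")

_PFAM_RE = re.compile(r"^PF\d{5}(\.\d+)?$")

#: Logic trees are plain YAML-friendly structures: a leaf is an enzyme name
#: (str); an internal node is a one-key dict {"all": [...]} or {"any": [...]}.
LogicNode = Union[str, Mapping[str, list]]


def strip_pfam_version(accession: str) -> str:
    """Return the accession without its version suffix ("PF06052.11" -> "PF06052")."""
    return accession.split(".", 1)[0]


def is_pfam_accession(accession: str) -> bool:
    return bool(_PFAM_RE.match(accession))


def pfam_equal(a: str, b: str) -> bool:
    """Versionless Pfam accession comparison."""
    return strip_pfam_version(a) == strip_pfam_version(b)


def logic_leaves(node: LogicNode) -> list[str]:
    """All enzyme names referenced by a logic tree, in declaration order."""
    if isinstance(node, str):
        return [node]
    leaves: list[str] = []
    for children in node.values():
        for child in children:
            leaves.extend(logic_leaves(child))
    return leaves


def eval_logic(node: LogicNode, satisfied: Mapping[str, bool]) -> bool:
    """Evaluate an AND/OR tree given per-leaf satisfaction."""
    if isinstance(node, str):
        return bool(satisfied[node])
    (op, children), = node.items()
    if op == "all":
        return all(eval_logic(c, satisfied) for c in children)
    if op == "any":
        return any(eval_logic(c, satisfied) for c in children)
    raise ValueError(f"unknown logic operator {op!r}")


@dataclass(frozen=True)
class EnzymeSpec:
    """One enzyme (or subunit) that can serve as an evidence leaf."""

    name: str
    ec_number: str = ""
    pfam_accessions: tuple[str, ...] = ()
    evidence_kind: str = "domain"  # "domain" | "homolog"
    query_tags: tuple[str, ...] = ()

    def __post_init__(self):
        object.__setattr__(self, "pfam_accessions", tuple(self.pfam_accessions))
        object.__setattr__(self, "query_tags", tuple(self.query_tags))


@dataclass(frozen=True)
class ClusterRequirement:
    """Co-location requirement: the named roles must sit in one gene neighborhood.

    ``max_gap_genes`` counts intervening genes allowed between consecutive
    member genes (rank units, not base pairs).
    """

    member_roles: tuple[str, ...]
    max_gap_genes: int = 3
    same_contig: bool = True
    same_strand: bool = False

    def __post_init__(self):
        object.__setattr__(self, "member_roles", tuple(self.member_roles))


@dataclass(frozen=True)
class PathwayRule:
    metabolite: str
    logic: LogicNode
    cluster: ClusterRequirement | None = None


@dataclass(frozen=True)
class TransporterSpec:
    name: str
    mode: str  # "proximity_to_anchor" | "homolog"
    anchor_enzyme: str = ""
    pfam_accessions: tuple[str, ...] = ()
    query_tags: tuple[str, ...] = ()

    def __post_init__(self):
        object.__setattr__(self, "pfam_accessions", tuple(self.pfam_accessions))
        object.__setattr__(self, "query_tags", tuple(self.query_tags))


@dataclass(frozen=True)
class Catalog:
    enzyme_specs: Mapping[str, EnzymeSpec]
    pathway_rules: tuple[PathwayRule, ...]
    transporter_specs: tuple[TransporterSpec, ...]

    def __post_init__(self):
        object.__setattr__(self, "enzyme_specs", dict(self.enzyme_specs))
        object.__setattr__(self, "pathway_rules", tuple(self.pathway_rules))
        object.__setattr__(self, "transporter_specs", tuple(self.transporter_specs))

    def rule_for(self, metabolite: str) -> PathwayRule:
        for rule in self.pathway_rules:
            if rule.metabolite == metabolite:
                return rule
        raise KeyError(metabolite)

    def transporter(self, name: str) -> TransporterSpec:
        for spec in self.transporter_specs:
            if spec.name == name:
                return spec
        raise KeyError(name)


# Fld* subunit and TnaB domain accessions live in curated supplementary data we
# do not ship; these placeholder accessions are syntactically valid, collide
# with nothing real, and are meant to be overridden via load_catalog.
_PLACEHOLDER_FLD = {
    "FldA": "PF99901",
    "FldB": "PF99902",
    "FldC": "PF99903",
    "FldI": "PF99904",
    "FldL": "PF99905",
}
_PLACEHOLDER_TNAB_DOMAIN = "PF99906"


def default_catalog() -> Catalog:
    """The shipped TRYP-6 rulebook.

    - kynurenine: Trp_dioxygenase domain (PF03301) of TDO alone is diagnostic.
    - quinolinate: AND of the 3-HAO (PF06052), FAD_binding_3 (PF01494) and
      Aminotran_5 (PF00266) domains, carried by HAD, KMO and KYN respectively.
    - indole: tryptophanase homolog (BLAST evidence).
    - IAA: homolog of tryptophan 2-monooxygenase (EC 1.13.12.3) OR of
      indolepyruvate decarboxylase (EC 4.1.1.74) — alternate routes.
    - IPA: all five Fld roles (phenyllactate dehydratase FldABC, activator
      FldI, AMP-binding FldL) present AND clustered in one gene neighborhood.
    - tryptamine: tryptophan decarboxylase homolog (EC 4.1.1.28).
    """
    enzymes = {
        "TDO": EnzymeSpec("TDO", "1.13.11.11", ("PF03301",), "domain"),
        "KMO": EnzymeSpec("KMO", "1.14.13.9", ("PF01494",), "domain"),
        "KYN": EnzymeSpec("KYN", "3.7.1.3", ("PF00266",), "domain"),
        "HAD": EnzymeSpec("HAD", "1.13.11.6", ("PF06052",), "domain"),
        "tryptophanase": EnzymeSpec(
            "tryptophanase", "4.1.99.1", (), "homolog", ("tnaA_ECOLI",)
        ),
        "tryptophan_2_monooxygenase": EnzymeSpec(
            "tryptophan_2_monooxygenase", "1.13.12.3", (), "homolog", ("iaaM_PSESY",)
        ),
        "indolepyruvate_decarboxylase": EnzymeSpec(
            "indolepyruvate_decarboxylase", "4.1.1.74", (), "homolog", ("ipdC_ENTCL",)
        ),
        "tryptophan_decarboxylase": EnzymeSpec(
            "tryptophan_decarboxylase",
            "4.1.1.28",
            (),
            "homolog",
            ("tdc_CLOSG", "tdc_RUMGN"),
        ),
    }
    for role, acc in _PLACEHOLDER_FLD.items():
        enzymes[role] = EnzymeSpec(role, "", (acc,), "domain")

    fld_roles = tuple(_PLACEHOLDER_FLD)
    rules = (
        PathwayRule("kynurenine", "TDO"),
        PathwayRule("quinolinate", {"all": ["HAD", "KMO", "KYN"]}),
        PathwayRule("indole", "tryptophanase"),
        PathwayRule(
            "IAA",
            {"any": ["tryptophan_2_monooxygenase", "indolepyruvate_decarboxylase"]},
        ),
        PathwayRule(
            "IPA",
            {"all": list(fld_roles)},
            cluster=ClusterRequirement(fld_roles, max_gap_genes=3,
                                       same_contig=True, same_strand=False),
        ),
        PathwayRule("tryptamine", "tryptophan_decarboxylase"),
    )
    transporters = (
        TransporterSpec(
            "TnaB",
            "proximity_to_anchor",
            anchor_enzyme="tryptophanase",
            pfam_accessions=(_PLACEHOLDER_TNAB_DOMAIN,),
        ),
        TransporterSpec("AroP", "homolog", query_tags=("aroP_ECOLI", "aroP_CORGL")),
        TransporterSpec("Mtr", "homolog", query_tags=("mtr_ECOLI",)),
    )
    return Catalog(enzymes, rules, transporters)


def validate_catalog(catalog: Catalog) -> list[str]:
    """Return the list of invariant violations (empty iff the catalog is valid)."""
    v: list[str] = []
    for name, spec in catalog.enzyme_specs.items():
        if name != spec.name:
            v.append(f"enzyme {name!r}: key does not match spec name {spec.name!r}")
        for acc in spec.pfam_accessions:
            if not is_pfam_accession(acc):
                v.append(f"enzyme {name!r}: accession {acc!r} does not match "
                         "the Pfam pattern PF+5 digits")
        if spec.evidence_kind == "homolog" and not spec.query_tags:
            v.append(f"enzyme {name!r}: homolog evidence requires query_tags")
        elif spec.evidence_kind == "domain" and not spec.pfam_accessions:
            v.append(f"enzyme {name!r}: domain evidence requires pfam_accessions")
        elif spec.evidence_kind not in ("domain", "homolog"):
            v.append(f"enzyme {name!r}: unknown evidence_kind {spec.evidence_kind!r}")

    seen = [r.metabolite for r in catalog.pathway_rules]
    for m in METABOLITES:
        if m not in seen:
            v.append(f"catalog is missing a pathway rule for {m!r}")
    for m in seen:
        if m not in METABOLITES:
            v.append(f"pathway rule for unknown metabolite {m!r}")
        elif seen.count(m) > 1:
            v.append(f"duplicate pathway rule for {m!r}")

    for rule in catalog.pathway_rules:
        try:
            leaves = logic_leaves(rule.logic)
        except Exception:
            v.append(f"rule {rule.metabolite!r}: malformed logic tree")
            continue
        if not leaves:
            v.append(f"rule {rule.metabolite!r}: empty logic tree")
        for leaf in leaves:
            if leaf not in catalog.enzyme_specs:
                v.append(f"rule {rule.metabolite!r}: leaf {leaf!r} names no "
                         "enzyme defined in this catalog")
        if rule.cluster is not None:
            cl = rule.cluster
            if len(cl.member_roles) < 2:
                v.append(f"rule {rule.metabolite!r}: cluster needs >=2 member roles")
            if cl.max_gap_genes < 0:
                v.append(f"rule {rule.metabolite!r}: cluster max_gap_genes < 0")
            if not cl.same_contig:
                v.append(f"rule {rule.metabolite!r}: cluster same_contig must be true")
            for role in cl.member_roles:
                if role not in catalog.enzyme_specs:
                    v.append(f"rule {rule.metabolite!r}: cluster role {role!r} "
                             "names no enzyme defined in this catalog")

    names = [t.name for t in catalog.transporter_specs]
    if sorted(names) != sorted(TRANSPORTERS):
        v.append(f"transporter specs must be exactly {TRANSPORTERS}, got {tuple(names)}")
    for t in catalog.transporter_specs:
        if t.name == "TnaB":
            if t.mode != "proximity_to_anchor":
                v.append("TnaB must use proximity_to_anchor mode")
            elif t.anchor_enzyme != "tryptophanase":
                v.append("TnaB anchor_enzyme must be tryptophanase")
            if not t.pfam_accessions:
                v.append("TnaB requires a Pfam accession for its domain")
        elif t.name in ("AroP", "Mtr"):
            if t.mode != "homolog":
                v.append(f"{t.name} must use homolog mode")
            elif not t.query_tags:
                v.append(f"{t.name}: homolog mode requires query_tags")
        if t.mode == "proximity_to_anchor" and t.anchor_enzyme and \
                t.anchor_enzyme not in catalog.enzyme_specs:
            v.append(f"transporter {t.name!r}: anchor enzyme {t.anchor_enzyme!r} "
                     "names no enzyme defined in this catalog")
        for acc in t.pfam_accessions:
            if not is_pfam_accession(acc):
                v.append(f"transporter {t.name!r}: accession {acc!r} does not "
                         "match the Pfam pattern PF+5 digits")
    return v


# ---------------------------------------------------------------------------
# YAML serialization


def _logic_to_yaml(node: LogicNode):
    if isinstance(node, str):
        return node
    (op, children), = node.items()
    return {op: [_logic_to_yaml(c) for c in children]}


def dump_catalog(catalog: Catalog) -> str:
    """Serialize a catalog to its YAML config dialect."""
    doc = {
        "enzymes": {
            name: {
                "ec_number": spec.ec_number,
                "pfam_accessions": list(spec.pfam_accessions),
                "evidence_kind": spec.evidence_kind,
                "query_tags": list(spec.query_tags),
            }
            for name, spec in sorted(catalog.enzyme_specs.items())
        },
        "pathways": {
            rule.metabolite: {
                "logic": _logic_to_yaml(rule.logic),
                **(
                    {
                        "cluster": {
                            "member_roles": list(rule.cluster.member_roles),
                            "max_gap_genes": rule.cluster.max_gap_genes,
                            "same_contig": rule.cluster.same_contig,
                            "same_strand": rule.cluster.same_strand,
                        }
                    }
                    if rule.cluster is not None
                    else {}
                ),
            }
            for rule in catalog.pathway_rules
        },
        "transporters": {
            t.name: {
                "mode": t.mode,
                "anchor_enzyme": t.anchor_enzyme,
                "pfam_accessions": list(t.pfam_accessions),
                "query_tags": list(t.query_tags),
            }
            for t in catalog.transporter_specs
        },
    }
    return yaml.safe_dump(doc, sort_keys=False)


def _merge_enzyme(base: EnzymeSpec | None, name: str, cfg: Mapping) -> EnzymeSpec:
    if base is None:
        base = EnzymeSpec(name)
    kwargs = {}
    for key in ("ec_number", "evidence_kind"):
        if key in cfg:
            kwargs[key] = cfg[key]
    for key in ("pfam_accessions", "query_tags"):
        if key in cfg:
            kwargs[key] = tuple(cfg[key])
    return replace(base, **kwargs)


def _merge_rule(base: PathwayRule | None, metabolite: str, cfg: Mapping) -> PathwayRule:
    logic = cfg.get("logic", base.logic if base else None)
    if logic is None:
        raise CatalogConfigError(f"pathway {metabolite!r}: no logic tree given "
                                 "and no default to inherit")
    cluster = base.cluster if base else None
    if "cluster" in cfg:
        ccfg = cfg["cluster"]
        if ccfg is None:
            cluster = None
        else:
            ckw = {
                "member_roles": tuple(
                    ccfg.get("member_roles",
                             cluster.member_roles if cluster else ())
                ),
            }
            for key in ("max_gap_genes", "same_contig", "same_strand"):
                if key in ccfg:
                    ckw[key] = ccfg[key]
                elif cluster is not None:
                    ckw[key] = getattr(cluster, key)
            cluster = ClusterRequirement(**ckw)
    return PathwayRule(metabolite, logic, cluster)


def _merge_transporter(base: TransporterSpec | None, name: str,
                       cfg: Mapping) -> TransporterSpec:
    if base is None:
        base = TransporterSpec(name, cfg.get("mode", "homolog"))
    kwargs = {}
    for key in ("mode", "anchor_enzyme"):
        if key in cfg:
            kwargs[key] = cfg[key]
    for key in ("pfam_accessions", "query_tags"):
        if key in cfg:
            kwargs[key] = tuple(cfg[key])
    return replace(base, **kwargs)


def load_catalog(path) -> Catalog:
    """Load a catalog config, inheriting unspecified fields from the default.

    Raises :class:`CatalogConfigError` on parse failure (naming the line where
    possible) and :class:`CatalogValidationError` listing every invariant
    violation of the merged catalog.
    """
    text = Path(path).read_text()
    try:
        doc = yaml.safe_load(text) or {}
    except yaml.YAMLError as exc:
        mark = getattr(exc, "problem_mark", None)
        where = f" at line {mark.line + 1}" if mark is not None else ""
        raise CatalogConfigError(f"cannot parse catalog config {path}{where}: {exc}")
    if not isinstance(doc, Mapping):
        raise CatalogConfigError(f"catalog config {path} must be a mapping")

    base = default_catalog()
    enzymes = dict(base.enzyme_specs)
    for name, cfg in (doc.get("enzymes") or {}).items():
        enzymes[name] = _merge_enzyme(enzymes.get(name), name, cfg or {})

    rules = {r.metabolite: r for r in base.pathway_rules}
    for metabolite, cfg in (doc.get("pathways") or {}).items():
        rules[metabolite] = _merge_rule(rules.get(metabolite), metabolite, cfg or {})

    transporters = {t.name: t for t in base.transporter_specs}
    for name, cfg in (doc.get("transporters") or {}).items():
        transporters[name] = _merge_transporter(transporters.get(name), name, cfg or {})

    catalog = Catalog(
        enzymes,
        tuple(rules[m] for m in METABOLITES if m in rules)
        + tuple(r for m, r in rules.items() if m not in METABOLITES),
        tuple(transporters[n] for n in TRANSPORTERS if n in transporters)
        + tuple(t for n, t in transporters.items() if n not in TRANSPORTERS),
    )
    violations = validate_catalog(catalog)
    if violations:
        raise CatalogValidationError(violations)
    return catalog
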
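"""Signature-residue profiles for mercury-detoxification proteins.

A :class:`SignatureProfile` names the residues, in reference-protein
numbering, that a candidate homolog must carry to be called functional.
Two built-in profiles are shipped:

``MerA`` (mercuric reductase; numbering follows MerA of *Bacillus cereus*
RC607): the redox-active cysteine pair C207/C212, the conserved Y264, the
domain-conditional position 605 (tyrosine in bacterial homologs,
phenylalanine in archaeal homologs — the swapped residue is retained as the
"605-variant" class), and the C-terminal vicinal cysteine pair C628/C629.

``MerB`` (organomercurial lyase; numbering follows MerB of the *E. coli*
plasmid R831b): the catalytic C96, D99 (serine here defines the MerB-like
"99Ser" class), C117 (any substitution defines the MerB-like "117alt"
class), and C159.

Profiles store positions in the reference protein's own ungapped 1-based
numbering; translating those numbers through a gapped alignment is the job
of :mod:`merscreen.alnmap`.
"""

from __future__ import annotations

import io
import tomllib
from dataclasses import dataclass, field, replace

__all__ = [
    "SignaturePosition",
    "SignatureProfile",
    "UnknownProfileError",
    "ProfileConfigError",
    "builtin_profile",
    "load_profile",
    "loads_profile",
    "serialize_profile",
    "AMINO_ACIDS",
    "AMBIGUOUS_RESIDUE",
]

#: The 20 standard amino-acid letters.
AMINO_ACIDS = frozenset("ACDEFGHIKLMNPQRSTVWY")

#: Placeholder for an undetermined residue; screening treats it as
#: "ambiguous", never as evidence for or against function.
AMBIGUOUS_RESIDUE = "X"


class UnknownProfileError(KeyError):
    """Requested built-in profile does not exist."""


class ProfileConfigError(ValueError):
    """Profile configuration is malformed."""


@dataclass(frozen=True)
class VariantRule:
    """Residue set mapped to a named variant class.

    ``residues=None`` is a wildcard: any residue not otherwise accounted
    for receives ``label``. ``warn`` marks labels that are retained but
    flagged for auditing (e.g. a residue at MerB position 99 that is
    neither D nor S).
    """

    residues: frozenset[str] | None
    label: str
    warn: bool = False


@dataclass(frozen=True)
class SignaturePosition:
    """One reference-numbered residue requirement.

    Parameters
    ----------
    ref_position
        1-based residue number in the reference protein's ungapped
        sequence.
    canonical_residues
        Residues accepted as canonical at this position.
    variant_rules
        Ordered rules mapping non-canonical residues to variant labels.
    reject_on_other
        If true, a residue outside the canonical and variant sets
        invalidates the homolog call.
    essential
        Essential positions reject on failure (wrong residue with
        ``reject_on_other``, a gap, or a missing position).
    """

    ref_position: int
    canonical_residues: frozenset[str]
    variant_rules: tuple[VariantRule, ...] = ()
    reject_on_other: bool = True
    essential: bool = True

    def __post_init__(self) -> None:
        if self.ref_position < 1:
            raise ProfileConfigError(
                f"ref_position must be >= 1, got {self.ref_position}"
            )
        if not self.canonical_residues:
            raise ProfileConfigError(
                f"position {self.ref_position}: empty canonical residue set"
            )
        for rule in self.variant_rules:
            if rule.residues is not None and rule.residues & self.canonical_residues:
                raise ProfileConfigError(
                    f"position {self.ref_position}: canonical and variant "
                    f"residue sets overlap ({rule.label})"
                )


@dataclass(frozen=True)
class SignatureProfile:
    """A named set of signature-residue requirements.

    ``domain_conditional`` maps a taxonomic domain name to per-position
    overrides, replacing the base :class:`SignaturePosition` for records
    from that domain (used for MerA position 605). ``paired_positions``
    lists position pairs that must jointly hold, e.g. the vicinal
    C628/C629 pair at the MerA carboxy terminus.
    """

    name: str
    reference_id: str
    positions: tuple[SignaturePosition, ...]
    paired_positions: tuple[tuple[int, int], ...] = ()
    domain_conditional: dict[str, dict[int, SignaturePosition]] = field(
        default_factory=dict
    )

    def __post_init__(self) -> None:
        nums = [p.ref_position for p in self.positions]
        if len(nums) != len(set(nums)):
            raise ProfileConfigError(f"profile {self.name}: duplicate ref_position")
        known = set(nums)
        for a, b in self.paired_positions:
            if a not in known or b not in known:
                raise ProfileConfigError(
                    f"profile {self.name}: paired position ({a},{b}) not declared"
                )
        for domain, overrides in self.domain_conditional.items():
            for num in overrides:
                if num not in known:
                    raise ProfileConfigError(
                        f"profile {self.name}: domain override for undeclared "
                        f"position {num} ({domain})"
                    )

    def position_for(self, ref_position: int, domain: str | None) -> SignaturePosition:
        """Resolve the rule for ``ref_position`` under taxonomic ``domain``.

        Unknown domains (``None``) fall back to a permissive union of all
        domain-specific canonical sets, since a domain-conditional rule
        cannot be applied blind.
        """
        base = next(p for p in self.positions if p.ref_position == ref_position)
        if ref_position not in {
            n for ov in self.domain_conditional.values() for n in ov
        }:
            return base
        if domain is not None and domain in self.domain_conditional:
            return self.domain_conditional[domain].get(ref_position, base)
        # Unknown domain: accept any residue canonical under some domain.
        union = set(base.canonical_residues)
        for overrides in self.domain_conditional.values():
            if ref_position in overrides:
                union |= overrides[ref_position].canonical_residues
        return replace(base, canonical_residues=frozenset(union), variant_rules=())

    @property
    def ref_positions(self) -> tuple[int, ...]:
        return tuple(p.ref_position for p in self.positions)


def _mera_profile() -> SignatureProfile:
    cys = frozenset("C")
    positions = (
        SignaturePosition(207, cys),
        SignaturePosition(212, cys),
        SignaturePosition(264, frozenset("Y")),
        # Base rule for 605 is never used directly for Bacteria/Archaea;
        # see domain_conditional. It also serves unknown-domain fallback.
        SignaturePosition(
            605,
            frozenset("Y"),
            variant_rules=(VariantRule(frozenset("F"), "605-variant"),),
            reject_on_other=True,
            essential=False,
        ),
        SignaturePosition(628, cys),
        SignaturePosition(629, cys),
    )
    domain_conditional = {
        "Bacteria": {
            605: SignaturePosition(
                605,
                frozenset("Y"),
                variant_rules=(VariantRule(frozenset("F"), "605-variant"),),
                reject_on_other=True,
                essential=False,
            )
        },
        "Archaea": {
            605: SignaturePosition(
                605,
                frozenset("F"),
                variant_rules=(VariantRule(frozenset("Y"), "605-variant"),),
                reject_on_other=True,
                essential=False,
            )
        },
    }
    return SignatureProfile(
        name="MerA",
        reference_id="MerA_Bacillus_cereus_RC607",
        positions=positions,
        paired_positions=((628, 629),),
        domain_conditional=domain_conditional,
    )


def _merb_profile() -> SignatureProfile:
    positions = (
        SignaturePosition(96, frozenset("C")),
        SignaturePosition(
            99,
            frozenset("D"),
            variant_rules=(
                VariantRule(frozenset("S"), "99Ser"),
                VariantRule(None, "unclassified-99", warn=True),
            ),
            reject_on_other=False,
            essential=False,
        ),
        SignaturePosition(
            117,
            frozenset("C"),
            variant_rules=(VariantRule(None, "117alt"),),
            reject_on_other=False,
            essential=False,
        ),
        SignaturePosition(159, frozenset("C")),
    )
    return SignatureProfile(
        name="MerB",
        reference_id="MerB_plasmid_R831b",
        positions=positions,
    )


_BUILTINS = {"MerA": _mera_profile, "MerB": _merb_profile}


def builtin_profile(name: str) -> SignatureProfile:
    """Return a built-in signature profile (``"MerA"`` or ``"MerB"``)."""
    try:
        factory = _BUILTINS[name]
    except KeyError:
        raise UnknownProfileError(
            f"no built-in profile {name!r}; choose from {sorted(_BUILTINS)}"
        ) from None
    return factory()


# ---------------------------------------------------------------------------
# Config-file round trip (TOML: one [[position]] table per signature position,
# optional [[pair]] and [domain.<name>.<pos>] overrides).
# ---------------------------------------------------------------------------


def _position_to_toml(p: SignaturePosition, header: str) -> str:
    out = [f"[[{header}]]"]
    out.append(f"ref_position = {p.ref_position}")
    out.append(f'canonical = "{"".join(sorted(p.canonical_residues))}"')
    out.append(f"reject_on_other = {str(p.reject_on_other).lower()}")
    out.append(f"essential = {str(p.essential).lower()}")
    for rule in p.variant_rules:
        res = "*" if rule.residues is None else "".join(sorted(rule.residues))
        out.append(f"[[{header}.variant]]")
        out.append(f'residues = "{res}"')
        out.append(f'label = "{rule.label}"')
        out.append(f"warn = {str(rule.warn).lower()}")
    return "\n".join(out)


def serialize_profile(profile: SignatureProfile) -> str:
    """Serialize a profile to its TOML config representation."""
    out = [f'name = "{profile.name}"', f'reference_id = "{profile.reference_id}"']
    if profile.paired_positions:
        pairs = ", ".join(f"[{a}, {b}]" for a, b in profile.paired_positions)
        out.append(f"paired_positions = [{pairs}]")
    out.append("")
    for p in profile.positions:
        out.append(_position_to_toml(p, "position"))
        out.append("")
    for domain, overrides in profile.domain_conditional.items():
        for p in overrides.values():
            out.append(_position_to_toml(p, f'domain."{domain}".position'))
            out.append("")
    return "\n".join(out)


def _parse_position(tbl: dict) -> SignaturePosition:
    try:
        ref_position = int(tbl["ref_position"])
        canonical = frozenset(tbl["canonical"])
    except KeyError as exc:
        raise ProfileConfigError(f"position block missing key {exc}") from None
    rules = []
    for rt in tbl.get("variant", []):
        res = rt["residues"]
        rules.append(
            VariantRule(
                residues=None if res == "*" else frozenset(res),
                label=rt["label"],
                warn=bool(rt.get("warn", False)),
            )
        )
    return SignaturePosition(
        ref_position=ref_position,
        canonical_residues=canonical,
        variant_rules=tuple(rules),
        reject_on_other=bool(tbl.get("reject_on_other", True)),
        essential=bool(tbl.get("essential", True)),
    )


def loads_profile(text: str) -> SignatureProfile:
    """Parse a profile from its TOML config text."""
    try:
        data = tomllib.loads(text)
    except tomllib.TOMLDecodeError as exc:
        raise ProfileConfigError(f"invalid profile config: {exc}") from None
    for key in ("name", "reference_id"):
        if key not in data:
            raise ProfileConfigError(f"profile config missing {key!r}")
    positions = tuple(_parse_position(t) for t in data.get("position", []))
    seen: set[int] = set()
    for p in positions:
        if p.ref_position in seen:
            raise ProfileConfigError(f"duplicate ref_position {p.ref_position}")
        seen.add(p.ref_position)
    pairs = tuple(
        (int(a), int(b)) for a, b in data.get("paired_positions", [])
    )
    domain_conditional = {
        domain: {
            int(p["ref_position"]): _parse_position(p)
            for p in sub.get("position", [])
        }
        for domain, sub in data.get("domain", {}).items()
    }
    return SignatureProfile(
        name=data["name"],
        reference_id=data["reference_id"],
        positions=positions,
        paired_positions=pairs,
        domain_conditional=domain_conditional,
    )


def load_profile(path_or_file) -> SignatureProfile:
    """Load a profile from a TOML config file path or text handle."""
    if isinstance(path_or_file, io.TextIOBase):
        return loads_profile(path_or_file.read())
    with open(path_or_file, "r", encoding="utf-8") as fh:
        return loads_profile(fh.read())
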
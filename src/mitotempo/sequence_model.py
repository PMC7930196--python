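"""Mitogenomes as rCRS-relative variant profiles.

A sample is represented not as a raw sequence but as the set of differences
(:class:`VariantCall`) it carries against the 16,569-bp revised Cambridge
Reference Sequence coordinate system, together with its age and haplogroup
metadata (:class:`MitoProfile`).  All downstream analyses operate on these
variant sets: pairwise distances are symmetric-difference counts after
applying a site-exclusion policy that removes the unstable indel regions
around positions 309, 522 and 16,193 and the 16,519 hotspot.

Coordinates are 1-based, closed-interval, rCRS numbering throughout.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field, replace
from importlib import resources
from pathlib import Path
from typing import Iterable, Literal, Mapping, Sequence

import pandas as pd
from Bio import SeqIO

MT_LENGTH = 16569
#: Age (years BP, 1950 convention) assigned to modern samples collected 2000 AD.
MODERN_AGE_BP = -50.0

VariantKind = Literal["substitution", "insertion", "deletion"]

#: Default haplogroup-prefix -> macrohaplogroup mapping.  R-derived West/East
#: Eurasian labels (H, V, U, K, J, T, B, F, P, R) fold into R; first-letter M,
#: N and L labels map to themselves / L-other.
DEFAULT_MACRO_MAP: dict[str, str] = {
    "M": "M", "C": "M", "D": "M", "E": "M", "G": "M", "Q": "M", "Z": "M",
    "N": "N", "A": "N", "I": "N", "S": "N", "W": "N", "X": "N", "Y": "N",
    "R": "R", "B": "R", "F": "R", "H": "R", "J": "R", "K": "R", "P": "R",
    "T": "R", "U": "R", "V": "R",
    "L": "L-other",
}


@dataclass(frozen=True, order=True)
class VariantCall:
    """One difference against the reference.

    ``position`` is the 1-based rCRS coordinate.  Deletions spanning several
    positions are recorded at their first position with the full deleted
    string, so one mutational event is one call.
    """

    position: int
    kind: VariantKind
    ref: str
    alt: str

    def __post_init__(self) -> None:
        if not 1 <= self.position <= MT_LENGTH:
            raise ValueError(f"position {self.position} outside [1, {MT_LENGTH}]")
        if self.kind not in ("substitution", "insertion", "deletion"):
            raise ValueError(f"unknown variant kind {self.kind!r}")
        if self.ref == self.alt:
            raise ValueError(f"ref == alt ({self.ref!r}) at {self.position}")
        if self.kind == "insertion" and not self.alt:
            raise ValueError("insertion with empty inserted string")
        if self.kind == "deletion" and not self.ref:
            raise ValueError("deletion with empty deleted string")


@dataclass(frozen=True)
class MitoProfile:
    """One sample: id, age (years BP), haplogroup labels and its variant set."""

    id: str
    age_bp: float
    haplogroup: str
    macrohaplogroup: str
    variants: frozenset[VariantCall] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        if self.age_bp < -70:
            raise ValueError(f"{self.id}: age_bp {self.age_bp} < -70")
        keys = {(v.position, v.kind, v.alt) for v in self.variants}
        if len(keys) != len(self.variants):
            raise ValueError(f"{self.id}: duplicate (position, kind, alt) variant")

    @property
    def is_modern(self) -> bool:
        return self.age_bp <= 0


@dataclass(frozen=True)
class ExclusionPolicy:
    """Sites and indel windows removed before any distance is counted.

    ``indel_windows`` drop *indel* calls only; ``excluded_sites`` drop every
    call (the 16,519 hotspot is excluded whatever the mutation type).
    """

    indel_windows: tuple[tuple[int, int], ...] = (
        (303, 315),
        (513, 524),
        (16180, 16195),
    )
    excluded_sites: frozenset[int] = frozenset({16519})

    def __post_init__(self) -> None:
        for lo, hi in self.indel_windows:
            if not (1 <= lo <= hi <= MT_LENGTH):
                raise ValueError(f"window ({lo}, {hi}) outside [1, {MT_LENGTH}]")

    def _in_window(self, position: int) -> bool:
        return any(lo <= position <= hi for lo, hi in self.indel_windows)

    def filter_variants(self, variants: Iterable[VariantCall]) -> frozenset[VariantCall]:
        kept = []
        for v in variants:
            if v.position in self.excluded_sites:
                continue
            if v.kind in ("insertion", "deletion") and self._in_window(v.position):
                continue
            kept.append(v)
        return frozenset(kept)


DEFAULT_POLICY = ExclusionPolicy()


def apply_exclusions(profile: MitoProfile, policy: ExclusionPolicy = DEFAULT_POLICY) -> MitoProfile:
    """Return the profile with excluded calls removed (idempotent)."""
    return replace(profile, variants=policy.filter_variants(profile.variants))


def pair_difference(
    a: MitoProfile, b: MitoProfile, policy: ExclusionPolicy = DEFAULT_POLICY
) -> int:
    """Number of mutational differences between two samples.

    The size of the symmetric difference of the two exclusion-filtered
    variant sets.  Symmetric, zero on identical profiles, and idempotent
    under repeated filtering.
    """
    return len(policy.filter_variants(a.variants) ^ policy.filter_variants(b.variants))


# ---------------------------------------------------------------------------
# reference sequence


def load_reference() -> str:
    """Return the packaged 16,569-bp reference string (synthetic stand-in).

    The packaged FASTA is a deterministic synthetic sequence with the rCRS
    length and coordinate system, not the real NC_012920 bases; every
    analysis in this package depends only on coordinates and on alleles
    relative to this reference, never on the reference content itself.
    """
    ref_path = resources.files("mitotempo.data") / "synthetic_rcrs.fasta"
    with resources.as_file(ref_path) as p:
        record = next(SeqIO.parse(str(p), "fasta"))
    seq = str(record.seq).upper()
    if len(seq) != MT_LENGTH:
        raise ValueError(f"packaged reference has length {len(seq)} != {MT_LENGTH}")
    return seq


def infer_macrohaplogroup(haplogroup: str, macro_map: Mapping[str, str] | None = None) -> str:
    """Map a haplogroup label to its macrohaplogroup by first-letter prefix."""
    mapping = DEFAULT_MACRO_MAP if macro_map is None else macro_map
    if not haplogroup:
        raise ValueError("empty haplogroup label")
    first = haplogroup[0].upper()
    if first not in mapping:
        raise ValueError(f"cannot map haplogroup {haplogroup!r} to a macrohaplogroup")
    return mapping[first]


# ---------------------------------------------------------------------------
# readers / writers

_SUB_RE = re.compile(r"^(\d+)([ACGT])$")
_INS_RE = re.compile(r"^(\d+)\.(\d+)([ACGT]+)$")
_DEL_RE = re.compile(r"^(\d+)d$")


def parse_variant_token(token: str, reference: str) -> VariantCall:
    """Parse one haplotype-table token.

    Dialect: ``73G`` substitution, ``315.1C`` insertion (the ``.1`` is the
    insertion index after the anchor position), ``522d`` single-site deletion.
    """
    token = token.strip()
    if m := _SUB_RE.match(token):
        pos, alt = int(m.group(1)), m.group(2)
        ref = reference[pos - 1]
        if ref == alt:
            raise ValueError(f"token {token!r}: alt equals reference base {ref}")
        return VariantCall(pos, "substitution", ref, alt)
    if m := _INS_RE.match(token):
        pos, alt = int(m.group(1)), m.group(3)
        return VariantCall(pos, "insertion", "-", alt)
    if m := _DEL_RE.match(token):
        pos = int(m.group(1))
        return VariantCall(pos, "deletion", reference[pos - 1], "-")
    raise ValueError(f"unparseable variant token {token!r}")


def format_variant_token(v: VariantCall) -> str:
    if v.kind == "substitution":
        return f"{v.position}{v.alt}"
    if v.kind == "insertion":
        return f"{v.position}.1{v.alt}"
    return f"{v.position}d"


def _read_metadata(metadata_path: str | Path, macro_map: Mapping[str, str] | None) -> pd.DataFrame:
    meta = pd.read_csv(metadata_path, dtype={"id": str})
    required = {"id", "age_bp", "haplogroup", "macrohaplogroup"}
    missing = required - set(meta.columns)
    if missing:
        raise ValueError(f"metadata missing columns: {sorted(missing)}")
    mapping = DEFAULT_MACRO_MAP if macro_map is None else macro_map
    known = set(mapping.values())
    for _, row in meta.iterrows():
        if row["macrohaplogroup"] not in known:
            raise ValueError(
                f"unknown macrohaplogroup {row['macrohaplogroup']!r} for sample {row['id']}"
            )
    return meta.set_index("id")


def _profile_from_meta(sid: str, meta: pd.DataFrame, variants: frozenset[VariantCall]) -> MitoProfile:
    if sid not in meta.index:
        raise ValueError(f"sample {sid!r} missing from metadata table")
    row = meta.loc[sid]
    return MitoProfile(
        id=sid,
        age_bp=float(row["age_bp"]),
        haplogroup=str(row["haplogroup"]),
        macrohaplogroup=str(row["macrohaplogroup"]),
        variants=variants,
    )


def call_variants(sequence: str, reference: str, sample_id: str = "?") -> frozenset[VariantCall]:
    """Call variants for one aligned 16,569-column sequence against the reference.

    Columns equal to the reference produce no call; an aligned base differing
    from the reference is a substitution; runs of ``-`` collapse into a single
    deletion recorded at the run's first position.  Insertions cannot occur in
    a fixed-column alignment and are only representable in haplotype tables.
    """
    sequence = sequence.upper()
    if len(sequence) != len(reference):
        raise ValueError(
            f"sequence {sample_id!r} has length {len(sequence)}, expected {len(reference)}"
        )
    calls: list[VariantCall] = []
    i = 0
    n = len(reference)
    while i < n:
        s, r = sequence[i], reference[i]
        if s == r:
            i += 1
            continue
        if s == "-":
            j = i
            while j < n and sequence[j] == "-":
                j += 1
            calls.append(VariantCall(i + 1, "deletion", reference[i:j], "-"))
            i = j
            continue
        if s == "N":  # missing data, not a call
            i += 1
            continue
        calls.append(VariantCall(i + 1, "substitution", r, s))
        i += 1
    return frozenset(calls)


def read_fasta_profiles(
    fasta_path: str | Path,
    metadata_path: str | Path,
    reference: str | None = None,
    macro_map: Mapping[str, str] | None = None,
) -> list[MitoProfile]:
    """Read aligned FASTA (16,569 columns) + metadata CSV into profiles."""
    ref = load_reference() if reference is None else reference
    meta = _read_metadata(metadata_path, macro_map)
    profiles = []
    for record in SeqIO.parse(str(fasta_path), "fasta"):
        variants = call_variants(str(record.seq), ref, sample_id=record.id)
        profiles.append(_profile_from_meta(record.id, meta, variants))
    if not profiles:
        raise ValueError(f"no sequences found in {fasta_path}")
    return profiles


def read_haplotype_table(
    table_path: str | Path,
    metadata_path: str | Path,
    reference: str | None = None,
    macro_map: Mapping[str, str] | None = None,
) -> list[MitoProfile]:
    """Read the tab-delimited haplotype dialect: ``id<TAB>73G 263G 315.1C``."""
    ref = load_reference() if reference is None else reference
    meta = _read_metadata(metadata_path, macro_map)
    profiles = []
    with open(table_path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            sid = parts[0].strip()
            tokens = parts[1].split() if len(parts) > 1 and parts[1].strip() else []
            variants = frozenset(parse_variant_token(t, ref) for t in tokens)
            profiles.append(_profile_from_meta(sid, meta, variants))
    return profiles


def write_haplotype_table(profiles: Sequence[MitoProfile], table_path: str | Path) -> None:
    """Write profiles in the haplotype-table dialect (round-trips with the reader)."""
    with open(table_path, "w") as fh:
        for p in profiles:
            tokens = " ".join(format_variant_token(v) for v in sorted(p.variants))
            fh.write(f"{p.id}\t{tokens}\n")


def write_metadata(profiles: Sequence[MitoProfile], metadata_path: str | Path) -> None:
    pd.DataFrame(
        {
            "id": [p.id for p in profiles],
            "age_bp": [p.age_bp for p in profiles],
            "haplogroup": [p.haplogroup for p in profiles],
            "macrohaplogroup": [p.macrohaplogroup for p in profiles],
        }
    ).to_csv(metadata_path, index=False)


def profile_to_sequence(profile: MitoProfile, reference: str) -> str:
    """Apply substitution/deletion calls to the reference (aligned, fixed columns).

    Insertions are skipped with a warning: a 16,569-column alignment cannot
    represent them.
    """
    seq = list(reference)
    for v in sorted(profile.variants):
        if v.kind == "substitution":
            seq[v.position - 1] = v.alt
        elif v.kind == "deletion":
            for k in range(len(v.ref)):
                seq[v.position - 1 + k] = "-"
        else:
            warnings.warn(
                f"{profile.id}: insertion at {v.position} not representable in "
                "fixed-column FASTA; skipped"
            )
    return "".join(seq)
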
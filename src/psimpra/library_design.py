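"""Design of massively parallel snoRNA-target reporter libraries.

An H/ACA box snoRNA hairpin carries an internal loop (the pseudouridylation
pocket) whose two single-stranded guide elements base-pair with target
sequence flanking a substrate uridine, leaving the uridine itself and the
base immediately 3' of it (the +1 position) unpaired.  This module builds
the designed-sequence side of the assay:

* synthetic snoRNA targets with graded complementarity to a pocket
  (levels (3,2), (5,4), (8,8), (10,10) bases upstream/downstream of the U),
  their +1-position mutation/deletion series and U->G negative controls;
* native rRNA/snRNA fragments, 75 nt long with the known pseudouridine at
  position 42 (1-based), plus U->G controls;
* the 729-sequence context-reporter set (a single T followed by all
  {A,C,G}^6 hexamers in an otherwise T-free backbone);
* synthetic snoRNAs retargeted at a chosen uridine by replacing the
  target-binding guide bases of a scaffold pocket.

All sequences are DNA-alphabet internally (T); U is accepted and normalized.
Coordinates are 0-based except where a name says otherwise.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .seqtools import hamming, max_homopolymer, normalize, revcomp

logger = logging.getLogger(__name__)

# ---------------------------------------------------------------------------
# Constants and configuration
# ---------------------------------------------------------------------------

#: Complementarity levels: bases paired upstream (5') of the target U and
#: downstream starting at +2; the +1 base is an unpaired G in every design.
LEVELS: Mapping[str, tuple[int, int]] = {
    "L3": (3, 2),
    "L5": (5, 4),
    "L8": (8, 8),
    "L10": (10, 10),
}

VARIANT_CLASSES = (
    "L3", "L5", "L8", "L10",
    "PLUS1_C", "PLUS1_A", "PLUS1_U", "PLUS1_DEL",
    "U2G_CONTROL", "NATIVE", "NATIVE_U2G",
)

#: Cloning-enzyme recognition sites screened against the Pol-II library.
DEFAULT_ENZYMES: Mapping[str, str] = {"AscI": "GGCGCGCC", "SpeI": "ACTAGT"}
#: Variant used for the Pol-I promoter plasmid.
POL1_ENZYMES: Mapping[str, str] = {"HindIII": "AAGCTT", "BamHI": "GGATCC"}

#: Shipped default 75-nt backbone hosting the complementarity patch at
#: slot 41 (0-based), mirroring "position 42" of the native fragments.
#: Free of the default restriction sites on both strands.
DEFAULT_BACKBONE = (
    "CATGCAGTCAAGCTAGACGATCCATGAGCTA"
    "CGATTACGAGCTTAGCAATCGGATCAATGCG"
    "ATCCAGACTGACG"
)
DEFAULT_PSI_SLOT = 41

#: Common adapters flanking every construct (synthetic defaults; the real
#: plasmid adapters are drop-in configuration).
DEFAULT_ADAPTER_5 = "ACGCAGAGTACGATGGACCA"
DEFAULT_ADAPTER_3 = "TGGAGCTCAGACCATCACGA"

NATIVE_WINDOW = 75
NATIVE_PSI_OFFSET = 41  # 0-based offset of the psi site = 1-based position 42


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PseudouridylationPocket:
    """One hairpin's pseudouridylation pocket.

    ``guide5`` is the pocket strand (5' side of the internal loop, written
    5'->3') that pairs with target bases 3' of the psi site; ``guide3`` is
    the 3'-side strand pairing with target bases 5' of the psi site.  Guide
    lengths are between 2 and 11 nt.  Optional half-open spans locate the
    guides within the full snoRNA sequence (needed only for retargeting).
    """

    snorna_id: str
    arm: int
    guide5: str
    guide3: str
    guide5_span: Optional[tuple[int, int]] = None
    guide3_span: Optional[tuple[int, int]] = None

    def __post_init__(self):
        object.__setattr__(self, "guide5", normalize(self.guide5))
        object.__setattr__(self, "guide3", normalize(self.guide3))
        if self.arm not in (1, 2):
            raise ValueError(f"{self.snorna_id}: arm must be 1 or 2, got {self.arm}")
        for name, g in (("guide5", self.guide5), ("guide3", self.guide3)):
            if not 2 <= len(g) <= 11:
                raise ValueError(
                    f"{self.snorna_id} arm {self.arm}: {name} length {len(g)} "
                    "outside [2, 11]"
                )

    @property
    def pocket_id(self) -> str:
        return f"{self.snorna_id}_a{self.arm}"


@dataclass
class TargetConstruct:
    """A designed reporter sequence.

    ``psi_index`` is the 0-based offset of the target U within
    ``variable_seq``; it is ``None`` for U->G controls.  ``full_seq`` is
    assembled (adapters + variable_seq + barcode) by the library-level
    functions once a barcode is assigned.
    """

    construct_id: str
    source: str
    variant_class: str
    variable_seq: str
    psi_index: Optional[int]
    barcode: Optional[str] = None
    full_seq: Optional[str] = None
    truncated: bool = False

    def __post_init__(self):
        self.variable_seq = normalize(self.variable_seq)
        if self.variant_class not in VARIANT_CLASSES:
            raise ValueError(f"unknown variant class {self.variant_class!r}")
        if self.psi_index is not None:
            if not 0 <= self.psi_index < len(self.variable_seq):
                raise ValueError(f"{self.construct_id}: psi_index out of range")
            if self.variable_seq[self.psi_index] != "T":
                raise ValueError(
                    f"{self.construct_id}: base at psi_index is "
                    f"{self.variable_seq[self.psi_index]}, expected T/U"
                )


@dataclass(frozen=True)
class NativeSite:
    """A known pseudouridine site windowed out of its host molecule."""

    molecule_id: str
    psi_position: int  # 1-based position on the molecule
    window_seq: str

    def __post_init__(self):
        object.__setattr__(self, "window_seq", normalize(self.window_seq))
        if len(self.window_seq) != NATIVE_WINDOW:
            raise ValueError(
                f"{self.molecule_id}:{self.psi_position}: window length "
                f"{len(self.window_seq)} != {NATIVE_WINDOW}"
            )
        if self.window_seq[NATIVE_PSI_OFFSET] != "T":
            raise ValueError(
                f"{self.molecule_id}:{self.psi_position}: window position 42 "
                f"holds {self.window_seq[NATIVE_PSI_OFFSET]}, expected T/U"
            )


@dataclass(frozen=True)
class ContextReporter:
    """A T-free backbone carrying one T followed by a {A,C,G}^6 hexamer."""

    hexamer: str
    full_seq: str

    def __post_init__(self):
        if len(self.hexamer) != 6 or set(self.hexamer) - set("ACG"):
            raise ValueError(f"hexamer {self.hexamer!r} is not 6 bases over A/C/G")
        if self.full_seq.count("T") != 1:
            raise ValueError("reporter must contain exactly one T")
        t = self.full_seq.index("T")
        if self.full_seq[t + 1 : t + 7] != self.hexamer:
            raise ValueError("the six bases after the T must equal the hexamer")


@dataclass(frozen=True)
class ReporterBackbone:
    """Backbone pieces for the context-reporter set.

    Every component must be T-free so the reporter's single T is the
    modification target.  The shipped promoter/primer strings are T-free
    synthetic stand-ins; real plasmid sequences can be dropped in.
    """

    spacer: str = "GACGCA"
    promoter: str = "GAACAGCGACCGAAGCGAGC"
    prefix40: str = "CAGACGGAACGCAGCAAGCGACAGCAGAACCGAGACGCAA"
    suffix64: str = (
        "GCAACGGCAGAACGCAGGACAGCGACCAGAACGGAAGCAC"
        "GACAGCGAACGCAGACCGCAAGCG"
    )
    rt_primer: str = "GCGGAACAGCCAGAAGACGG"

    def __post_init__(self):
        if len(self.prefix40) != 40 or len(self.suffix64) != 64:
            raise ValueError("prefix must be 40 nt and suffix 64 nt")
        for name in ("spacer", "promoter", "prefix40", "suffix64", "rt_primer"):
            seq = normalize(getattr(self, name))
            object.__setattr__(self, name, seq)
            if "T" in seq:
                raise ValueError(f"reporter backbone {name} contains a T")

    @property
    def t_offset(self) -> int:
        """0-based offset of the single T in an assembled reporter."""
        return len(self.spacer) + len(self.promoter) + len(self.prefix40)


# ---------------------------------------------------------------------------
# Synthetic snoRNA-target constructs
# ---------------------------------------------------------------------------

def build_synthetic_target(
    pocket: PseudouridylationPocket,
    level: str,
    backbone: str = DEFAULT_BACKBONE,
    psi_slot: int = DEFAULT_PSI_SLOT,
) -> TargetConstruct:
    """Embed a complementarity patch for ``pocket`` into ``backbone``.

    The upstream target bases pair antiparallel with the 3' guide
    element, the downstream bases (from +2 on) with the 5' element, and
    the +1 base is an unpaired guanosine.  The duplex is anchored at the
    psi-proximal guide ends (the loop bases adjacent to the upper stem:
    guide3's 5' end pairs target -1, guide5's 3' end pairs target +2), so
    the patch is ``revcomp(guide3[:up]) + T + G + revcomp(guide5[-down:])``
    and windows of different levels nest around the psi site.  Requested
    window lengths longer than a guide are truncated to the guide length
    and flagged.
    """
    if level not in LEVELS:
        raise ValueError(f"unknown complementarity level {level!r}")
    up_req, down_req = LEVELS[level]
    g5, g3 = pocket.guide5, pocket.guide3
    backbone = normalize(backbone)

    up = min(up_req, len(g3))
    down = min(down_req, len(g5))
    truncated = (up, down) != (up_req, down_req)
    if truncated:
        logger.warning(
            "%s %s: window (%d,%d) truncated to (%d,%d) by guide lengths",
            pocket.pocket_id, level, up_req, down_req, up, down,
        )

    patch = revcomp(g3[:up]) + "T" + "G" + revcomp(g5[-down:])
    start = psi_slot - up
    construct_id = f"{pocket.pocket_id}_{level}"
    if start < 0 or start + len(patch) > len(backbone):
        raise ValueError(
            f"{construct_id}: complementarity patch ({len(patch)} nt at "
            f"offset {start}) overruns the {len(backbone)}-nt backbone"
        )
    variable_seq = backbone[:start] + patch + backbone[start + len(patch):]
    return TargetConstruct(
        construct_id=construct_id,
        source=pocket.pocket_id,
        variant_class=level,
        variable_seq=variable_seq,
        psi_index=psi_slot,
        truncated=truncated,
    )


def build_plus1_series(construct_l10: TargetConstruct) -> list[TargetConstruct]:
    """+1-position perturbations of a maximal-complementarity construct.

    Returns the three point substitutions of the unpaired G at psi_index+1
    (to C, A or U/T) and the single-base deletion of that position, in the
    order PLUS1_C, PLUS1_A, PLUS1_U, PLUS1_DEL.  Only constructs with 10-nt
    complementarity carry this series.
    """
    if construct_l10.variant_class != "L10":
        raise ValueError(
            f"+1 series applies only to L10 constructs, got "
            f"{construct_l10.variant_class}"
        )
    seq, pi = construct_l10.variable_seq, construct_l10.psi_index
    base_id = construct_l10.construct_id.rsplit("_L10", 1)[0]
    out = []
    for cls, base in (("PLUS1_C", "C"), ("PLUS1_A", "A"), ("PLUS1_U", "T")):
        out.append(TargetConstruct(
            construct_id=f"{base_id}_{cls}",
            source=construct_l10.source,
            variant_class=cls,
            variable_seq=seq[: pi + 1] + base + seq[pi + 2 :],
            psi_index=pi,
            truncated=construct_l10.truncated,
        ))
    out.append(TargetConstruct(
        construct_id=f"{base_id}_PLUS1_DEL",
        source=construct_l10.source,
        variant_class="PLUS1_DEL",
        variable_seq=seq[: pi + 1] + seq[pi + 2 :],
        psi_index=pi,
        truncated=construct_l10.truncated,
    ))
    return out


def build_u2g_control(construct: TargetConstruct) -> TargetConstruct:
    """Negative control: mutate the target uridine to guanosine."""
    if construct.psi_index is None:
        raise ValueError(f"{construct.construct_id}: no psi_index to mutate")
    pi = construct.psi_index
    seq = construct.variable_seq
    cls = "NATIVE_U2G" if construct.variant_class == "NATIVE" else "U2G_CONTROL"
    return TargetConstruct(
        construct_id=f"{construct.construct_id}_U2G",
        source=construct.source,
        variant_class=cls,
        variable_seq=seq[:pi] + "G" + seq[pi + 1 :],
        psi_index=None,
        truncated=construct.truncated,
    )


# ---------------------------------------------------------------------------
# Native rRNA/snRNA fragments
# ---------------------------------------------------------------------------

def build_native_fragment(
    molecule_id: str, molecule_seq: str, psi_position: int
) -> Optional[NativeSite]:
    """Window a known psi site into a 75-mer with the site at position 42.

    ``psi_position`` is 1-based on the host molecule.  Sites closer than
    41 nt to the 5' end or 33 nt to the 3' end cannot be windowed and are
    skipped with a warning (returns None).
    """
    seq = normalize(molecule_seq)
    lo = psi_position - (NATIVE_PSI_OFFSET + 1)  # 0-based window start
    hi = lo + NATIVE_WINDOW
    if lo < 0 or hi > len(seq):
        logger.warning(
            "%s position %d too close to a molecule end for a %d-nt window; skipped",
            molecule_id, psi_position, NATIVE_WINDOW,
        )
        return None
    return NativeSite(molecule_id, psi_position, seq[lo:hi])


def native_site_constructs(site: NativeSite) -> list[TargetConstruct]:
    """NATIVE construct plus its NATIVE_U2G control for one windowed site."""
    native = TargetConstruct(
        construct_id=f"{site.molecule_id}_{site.psi_position}_NATIVE",
        source=f"{site.molecule_id}:{site.psi_position}",
        variant_class="NATIVE",
        variable_seq=site.window_seq,
        psi_index=NATIVE_PSI_OFFSET,
    )
    return [native, build_u2g_control(native)]


# ---------------------------------------------------------------------------
# Restriction screening and barcodes
# ---------------------------------------------------------------------------

def screen_restriction_sites(
    seq: str, enzyme_sites: Iterable[str] = tuple(DEFAULT_ENZYMES.values())
) -> bool:
    """True (= omit the design) iff any site occurs on either strand."""
    s = normalize(seq)
    for site in enzyme_sites:
        if not site:
            raise ValueError("empty restriction-site string")
        site = normalize(site)
        if site in s or revcomp(site) in s:
            return True
    return False


def assign_barcodes(
    constructs: Sequence[TargetConstruct],
    k: int = 8,
    seed: int = 0,
    enzyme_sites: Iterable[str] = tuple(DEFAULT_ENZYMES.values()),
    max_homopolymer_run: int = 4,
) -> list[str]:
    """Assign distinct k-mer barcodes to every construct (in place).

    Seeded rejection sampling: a candidate is kept iff it has no
    homopolymer run longer than ``max_homopolymer_run``, contains no
    restriction site on either strand, and is at Hamming distance >= 2
    from every barcode already assigned.
    """
    n = len(constructs)
    if 4 ** k < n:
        raise ValueError(f"4^{k} barcode space cannot host {n} constructs")
    enzyme_sites = [normalize(s) for s in enzyme_sites]
    rng = np.random.default_rng(seed)
    bases = np.array(list("ACGT"))
    accepted: list[str] = []
    attempts, max_attempts = 0, 500 * n + 10_000
    while len(accepted) < n:
        attempts += 1
        if attempts > max_attempts:
            raise RuntimeError(
                f"barcode space exhausted after assigning {len(accepted)} of {n}"
            )
        cand = "".join(bases[rng.integers(0, 4, size=k)])
        if max_homopolymer(cand) > max_homopolymer_run:
            continue
        if any(s in cand or revcomp(s) in cand for s in enzyme_sites):
            continue
        if any(hamming(cand, b) < 2 for b in accepted):
            continue
        accepted.append(cand)
    for c, b in zip(constructs, accepted):
        c.barcode = b
    return accepted


# ---------------------------------------------------------------------------
# Context reporters
# ---------------------------------------------------------------------------

def enumerate_context_reporters(
    backbone: ReporterBackbone = ReporterBackbone(),
) -> list[ContextReporter]:
    """All 3^6 = 729 reporters, one per {A,C,G}^6 hexamer, lexicographic."""
    head = backbone.spacer + backbone.promoter + backbone.prefix40
    tail = backbone.suffix64 + backbone.rt_primer
    out = []
    for combo in itertools.product("ACG", repeat=6):
        hexamer = "".join(combo)
        out.append(ContextReporter(hexamer, head + "T" + hexamer + tail))
    return out


# ---------------------------------------------------------------------------
# Synthetic snoRNA retargeting
# ---------------------------------------------------------------------------

def design_ptc_snorna(
    scaffold_snorna: str,
    scaffold_pocket: PseudouridylationPocket,
    target_window: str,
    target_u_index: int,
    replace5: int = 8,
    replace3: int = 3,
) -> str:
    """Retarget a scaffold snoRNA's pocket at a chosen uridine.

    Replaces the target-binding guide bases only — by default the 8
    psi-proximal (3'-terminal) bases of the pocket's 5' guide element and
    the 3 psi-proximal (5'-terminal) bases of its 3' element — with the
    reverse complement of the corresponding bases flanking
    ``target_u_index`` in ``target_window``; stems and H/ACA boxes are
    untouched.  The guide spans of ``scaffold_pocket`` must be annotated
    on the scaffold.
    """
    scaffold = normalize(scaffold_snorna)
    window = normalize(target_window)
    if window[target_u_index] != "T":
        raise ValueError(
            f"target base at index {target_u_index} is {window[target_u_index]}, "
            "expected U/T"
        )
    if scaffold_pocket.guide5_span is None or scaffold_pocket.guide3_span is None:
        raise ValueError("scaffold pocket guide spans are not annotated")
    g5s, g5e = scaffold_pocket.guide5_span
    g3s, g3e = scaffold_pocket.guide3_span
    if scaffold[g5s:g5e] != scaffold_pocket.guide5:
        raise ValueError("guide5 span does not match the scaffold sequence")
    if scaffold[g3s:g3e] != scaffold_pocket.guide3:
        raise ValueError("guide3 span does not match the scaffold sequence")
    if replace5 > g5e - g5s or replace3 > g3e - g3s:
        raise ValueError("replacement length exceeds a guide element")

    down = window[target_u_index + 2 : target_u_index + 2 + replace5]
    up = window[target_u_index - replace3 : target_u_index]
    if len(down) < replace5 or len(up) < replace3:
        raise ValueError("target window too short for the requested replacement")

    new = list(scaffold)
    # guide5 3'-tail pairs the downstream (+2 on) target bases, antiparallel
    new[g5e - replace5 : g5e] = revcomp(down)
    # guide3 5'-head pairs the upstream target bases, antiparallel
    new[g3s : g3s + replace3] = revcomp(up)
    return "".join(new)


# ---------------------------------------------------------------------------
# Library assembly, manifest and I/O
# ---------------------------------------------------------------------------

def assemble_full_seq(
    construct: TargetConstruct,
    adapter5: str = DEFAULT_ADAPTER_5,
    adapter3: str = DEFAULT_ADAPTER_3,
) -> str:
    """adapters + variable_seq + barcode; also records it on the construct."""
    if construct.barcode is None:
        raise ValueError(f"{construct.construct_id}: no barcode assigned")
    construct.full_seq = (
        normalize(adapter5) + construct.variable_seq + construct.barcode
        + normalize(adapter3)
    )
    return construct.full_seq


def design_synthetic_library(
    pockets: Sequence[PseudouridylationPocket],
    backbone: str = DEFAULT_BACKBONE,
    psi_slot: int = DEFAULT_PSI_SLOT,
    plus1_pockets: Optional[Iterable[str]] = None,
    enzymes: Mapping[str, str] = DEFAULT_ENZYMES,
    seed: int = 0,
    adapter5: str = DEFAULT_ADAPTER_5,
    adapter3: str = DEFAULT_ADAPTER_3,
) -> tuple[list[TargetConstruct], pd.DataFrame]:
    """The synthetic sub-library: per pocket, four complementarity levels
    and a U->G control of the L10 design; pockets named in
    ``plus1_pockets`` additionally carry the four +1-series variants.

    Returns the constructs (barcoded, assembled) and the design manifest;
    designs that create a cloning-enzyme site anywhere in the full
    sequence are flagged ``omitted`` in the manifest.
    """
    plus1 = set(plus1_pockets or [])
    constructs: list[TargetConstruct] = []
    for pocket in pockets:
        by_level = {
            lvl: build_synthetic_target(pocket, lvl, backbone, psi_slot)
            for lvl in LEVELS
        }
        constructs.extend(by_level.values())
        constructs.append(build_u2g_control(by_level["L10"]))
        if pocket.pocket_id in plus1 or pocket.snorna_id in plus1:
            constructs.extend(build_plus1_series(by_level["L10"]))
    _finalize(constructs, enzymes, seed, adapter5, adapter3)
    manifest = build_manifest(constructs, pockets, enzymes)
    return constructs, manifest


def design_native_library(
    sites: Iterable[tuple[str, int]],
    molecules: Mapping[str, str],
    enzymes: Mapping[str, str] = DEFAULT_ENZYMES,
    seed: int = 1,
    adapter5: str = DEFAULT_ADAPTER_5,
    adapter3: str = DEFAULT_ADAPTER_3,
) -> tuple[list[TargetConstruct], pd.DataFrame]:
    """The native sub-library: a windowed 75-mer and a U->G control per
    (molecule, 1-based psi position) pair; unwindowable sites are skipped
    with a warning."""
    constructs: list[TargetConstruct] = []
    for molecule_id, psi_position in sites:
        if molecule_id not in molecules:
            raise KeyError(f"no sequence for molecule {molecule_id!r}")
        site = build_native_fragment(molecule_id, molecules[molecule_id], psi_position)
        if site is not None:
            constructs.extend(native_site_constructs(site))
    _finalize(constructs, enzymes, seed, adapter5, adapter3)
    manifest = build_manifest(constructs, enzymes=enzymes)
    return constructs, manifest


def _finalize(constructs, enzymes, seed, adapter5, adapter3):
    assign_barcodes(constructs, seed=seed, enzyme_sites=tuple(enzymes.values()))
    for c in constructs:
        assemble_full_seq(c, adapter5, adapter3)


def build_manifest(
    constructs: Sequence[TargetConstruct],
    pockets: Sequence[PseudouridylationPocket] = (),
    enzymes: Mapping[str, str] = DEFAULT_ENZYMES,
) -> pd.DataFrame:
    """Design manifest with full-sequence psi coordinates and omission flags."""
    by_pocket = {p.pocket_id: p for p in pockets}
    adapter_offset = {
        c.construct_id: (c.full_seq.index(c.variable_seq) if c.full_seq else 0)
        for c in constructs
    }
    rows = []
    for c in constructs:
        omitted = screen_restriction_sites(c.full_seq or c.variable_seq,
                                           tuple(enzymes.values()))
        pocket = by_pocket.get(c.source)
        rows.append({
            "construct_id": c.construct_id,
            "snorna_id": pocket.snorna_id if pocket else "",
            "arm": pocket.arm if pocket else "",
            "variant_class": c.variant_class,
            "psi_index": (
                adapter_offset[c.construct_id] + c.psi_index
                if c.psi_index is not None else pd.NA
            ),
            "barcode": c.barcode or "",
            "omitted": omitted,
            "omit_reason": "restriction_site" if omitted else "",
        })
    return pd.DataFrame(rows)


def write_library_fasta(constructs: Sequence[TargetConstruct], path,
                        manifest: Optional[pd.DataFrame] = None) -> int:
    """Emit non-omitted constructs as FASTA (id = construct_id). Returns count."""
    omitted = set()
    if manifest is not None:
        omitted = set(manifest.loc[manifest["omitted"], "construct_id"])
    n = 0
    with open(path, "w") as fh:
        for c in constructs:
            if c.construct_id in omitted:
                continue
            fh.write(f">{c.construct_id}\n{c.full_seq or c.variable_seq}\n")
            n += 1
    return n


def read_pockets_tsv(path) -> list[PseudouridylationPocket]:
    """Pocket table: columns snorna_id, arm, guide5, guide3 (tab-separated)."""
    df = pd.read_csv(path, sep="\t", dtype={"snorna_id": str})
    return [
        PseudouridylationPocket(r.snorna_id, int(r.arm), r.guide5, r.guide3)
        for r in df.itertuples()
    ]
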
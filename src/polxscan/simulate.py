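"""Synthetic data with planted ground truth.

Two generators cover the two halves of the pipeline:

* :func:`simulate_msa` emits an alignment built on a fixed 575-residue
  template whose coordinates match the default reference windows and sites
  (triad, palm/fingers windows, dNTP-site motifs, nine-residue nuclease
  consensus).  Catalytic-triad classes, palm/fingers deletions and motif
  states are planted explicitly and recorded in :class:`MsaTruth`.
  Deletions are realized as gap runs against the template (no realignment),
  so window arithmetic is exact by construction.

* :func:`simulate_genomes` emits a gene table whose per-genome PolX and
  NHEJ statuses are drawn from a configurable joint distribution and
  realized exactly through role labels, optionally planting a
  co-directional operon-partner gene within the neighborhood bp cutoff.

Both are deterministic under a seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .alignment import Msa
from .features import DomainWindows
from .genomes import GeneRecord

AA20 = np.array(list("ACDEFGHIKLMNPQRSTVWY"))
NON_ACIDIC = np.array(list("AKRTVPGSNQ"))
ACIDIC = np.array(list("DE"))

PHP_CONSENSUS = "HHHEHHEDH"
PHP_VARIANTS = ("QHHEHHEDH", "HHPERHEDQ", "HHRERHEDC")

REFERENCE_ID = "REFERENCE"

# altered-state pools for the dNTP-binding sites, mirroring the kinds of
# replacements seen in degraded active sites
ALTERED_SITE_POOLS = {
    "gs_motif": ("GN", "AS", "AA"),
    "dntp_N": ("I", "L", "V", "F"),
    "dntp_basic": ("E", "A", "P"),
    "steric_gate": ("LF", "IV", "AF"),
    "palm_R": ("K", "Q"),
}


@dataclass(frozen=True)
class ScaffoldSpec:
    """Layout of the synthetic template, in template residue numbering."""

    template_length: int = 575
    domains: dict[str, tuple[int, int]] = field(
        default_factory=lambda: {
            "lyase_8kda": (1, 87),
            "thumb": (88, 177),
            "palm": (178, 279),
            "fingers": (280, 314),
            "php": (315, 575),
        }
    )
    triad_positions: tuple[int, int, int] = (190, 192, 256)
    site_positions: dict[str, tuple[int, ...]] = field(
        default_factory=lambda: {
            "dntp_basic": (276,),
            "dntp_N": (279,),
            "steric_gate": (271, 272),
            "gs_motif": (274, 275),
            "palm_R": (183,),
            "php_site": tuple(range(430, 439)),
        }
    )
    palm_window: tuple[int, int] = (178, 279)
    fingers_window: tuple[int, int] = (272, 314)
    # positions eligible for planted gap runs, chosen to avoid every
    # designated site so planted truth stays exact
    palm_deletion_zone: tuple[int, int] = (193, 255)
    fingers_deletion_zone: tuple[int, int] = (280, 314)

    @property
    def designated_positions(self) -> frozenset[int]:
        pos = set(self.triad_positions)
        for residues in self.site_positions.values():
            pos.update(residues)
        return frozenset(pos)

    @property
    def reference_site_states(self) -> dict[str, str]:
        template = build_template(self)
        return {
            name: "".join(template[p - 1] for p in residues)
            for name, residues in self.site_positions.items()
        }


def build_template(scaffold: ScaffoldSpec | None = None) -> str:
    """The fixed template sequence: pseudo-random background from a frozen
    seed, with the designated sites overwritten to their reference states."""
    scaffold = scaffold or ScaffoldSpec()
    rng = np.random.default_rng(987654321)
    seq = rng.choice(AA20, size=scaffold.template_length).tolist()
    t1, t2, t3 = scaffold.triad_positions
    for pos, ch in [(t1, "D"), (t2, "D"), (t3, "D")]:
        seq[pos - 1] = ch
    fixed_states = {
        "dntp_basic": "K",
        "dntp_N": "N",
        "steric_gate": "YF",
        "gs_motif": "GS",
        "palm_R": "R",
        "php_site": PHP_CONSENSUS,
    }
    for name, state in fixed_states.items():
        for pos, ch in zip(scaffold.site_positions[name], state):
            seq[pos - 1] = ch
    return "".join(seq)


def fixture_reference() -> tuple[ScaffoldSpec, str]:
    """The versioned scaffold and its template sequence."""
    scaffold = ScaffoldSpec()
    return scaffold, build_template(scaffold)


@dataclass(frozen=True)
class MsaTruth:
    """Planted per-sequence ground truth for a simulated alignment."""

    ref_id: str
    scaffold: ScaffoldSpec
    rows: dict[str, dict]  # seq_id -> planted facts


def _window_positions(window: tuple[int, int]) -> set[int]:
    return set(range(window[0], window[1] + 1))


def simulate_msa(
    n_seqs: int,
    f_altered: float = 0.3,
    f_palm_deletion: float = 0.0,
    f_fingers_deletion: float = 0.0,
    deletion_length_range: tuple[int, int] = (13, 26),
    substitution_rate: float = 0.05,
    seed: int = 0,
    f_indeterminate: float = 0.0,
    f_altered_motifs: float = 0.9,
    f_php_variant: float = 0.05,
    windows: DomainWindows | None = None,
    scaffold: ScaffoldSpec | None = None,
) -> tuple[Msa, MsaTruth]:
    """Simulate an alignment of ``n_seqs`` rows plus the ungapped reference.

    Per row: a triad class is drawn (altered with ``f_altered``,
    indeterminate with ``f_indeterminate``, else canonical) and realized by
    planting triad residues; palm/fingers gap runs of a length drawn from
    ``deletion_length_range`` are planted with the given probabilities;
    motif states are planted (altered rows receive degraded states with
    probability ``f_altered_motifs``); remaining positions mutate at
    ``substitution_rate``, never touching designated sites.
    """
    for name, f in [
        ("f_altered", f_altered),
        ("f_palm_deletion", f_palm_deletion),
        ("f_fingers_deletion", f_fingers_deletion),
        ("substitution_rate", substitution_rate),
        ("f_indeterminate", f_indeterminate),
    ]:
        if not 0.0 <= f <= 1.0:
            raise ValueError(f"{name} must be in [0, 1], got {f}")
    if n_seqs < 1:
        raise ValueError("n_seqs must be >= 1")
    if f_altered + f_indeterminate > 1.0:
        raise ValueError("f_altered + f_indeterminate must not exceed 1")

    scaffold = scaffold or ScaffoldSpec()
    windows = windows or DomainWindows(
        palm=scaffold.palm_window, fingers=scaffold.fingers_window
    )
    template = build_template(scaffold)
    lo, hi = deletion_length_range
    for zone, label in [
        (scaffold.palm_deletion_zone, "palm"),
        (scaffold.fingers_deletion_zone, "fingers"),
    ]:
        zone_size = zone[1] - zone[0] + 1
        if hi > zone_size:
            raise ValueError(
                f"deletion length {hi} exceeds the {label} deletion zone ({zone_size})"
            )
    if lo > hi or lo < 1:
        raise ValueError("invalid deletion_length_range")

    designated = scaffold.designated_positions
    mutable = np.array(
        [p for p in range(1, scaffold.template_length + 1) if p not in designated]
    )
    palm_positions = _window_positions(windows.palm)
    fingers_positions = _window_positions(windows.fingers)
    ref_states = scaffold.reference_site_states

    rng = np.random.default_rng(seed)
    records = [(REFERENCE_ID, template)]
    rows: dict[str, dict] = {}

    for i in range(n_seqs):
        seq_id = f"seq{i:05d}"
        seq = list(template)

        u = rng.random()
        if u < f_altered:
            cls = "altered"
        elif u < f_altered + f_indeterminate:
            cls = "indeterminate"
        else:
            cls = "canonical"

        # --- triad planting ---
        t_pos = scaffold.triad_positions
        if cls == "canonical":
            triad = rng.choice(ACIDIC, size=3, p=[0.85, 0.15])
        elif cls == "altered":
            n_non_acidic = int(rng.integers(1, 4))
            which = rng.choice(3, size=n_non_acidic, replace=False)
            triad = rng.choice(ACIDIC, size=3, p=[0.85, 0.15])
            triad[which] = rng.choice(NON_ACIDIC, size=n_non_acidic)
        else:
            triad = rng.choice(NON_ACIDIC, size=3)
            triad[int(rng.integers(0, 3))] = "X"
        for pos, ch in zip(t_pos, triad):
            seq[pos - 1] = ch

        # --- motif-state planting ---
        states = dict(ref_states)
        if cls == "altered":
            for site, pool in ALTERED_SITE_POOLS.items():
                if rng.random() < f_altered_motifs:
                    states[site] = pool[int(rng.integers(0, len(pool)))]
        if rng.random() < f_php_variant:
            states["php_site"] = PHP_VARIANTS[int(rng.integers(0, len(PHP_VARIANTS)))]
        for site, state in states.items():
            for pos, ch in zip(scaffold.site_positions[site], state):
                seq[pos - 1] = ch

        # --- background substitutions (designated sites excluded) ---
        hit = rng.random(len(mutable)) < substitution_rate
        new_res = rng.choice(AA20, size=int(hit.sum()))
        for pos, ch in zip(mutable[hit], new_res):
            seq[pos - 1] = ch

        # --- planted deletions as gap runs ---
        deleted: set[int] = set()
        for f_del, zone in [
            (f_palm_deletion, scaffold.palm_deletion_zone),
            (f_fingers_deletion, scaffold.fingers_deletion_zone),
        ]:
            if rng.random() < f_del:
                length = int(rng.integers(lo, hi + 1))
                start = int(rng.integers(zone[0], zone[1] - length + 2))
                for pos in range(start, start + length):
                    seq[pos - 1] = "-"
                    deleted.add(pos)

        palm_length = len(palm_positions - deleted)
        fingers_length = len(fingers_positions - deleted)
        palm_trunc = palm_length < windows.palm_truncation_threshold
        fingers_trunc = fingers_length < windows.fingers_truncation_threshold
        rows[seq_id] = {
            "triad_class": cls,
            "triad": "".join(triad),
            "palm_length": palm_length,
            "fingers_length": fingers_length,
            "palm_truncated": palm_trunc,
            "fingers_truncated": fingers_trunc,
            "double_truncated": palm_trunc and fingers_trunc,
            "full_length": scaffold.template_length - len(deleted),
            "motif_states": states,
        }
        records.append((seq_id, "".join(seq)))

    msa = Msa.from_pairs(records)
    return msa, MsaTruth(ref_id=REFERENCE_ID, scaffold=scaffold, rows=rows)


# ---------------------------------------------------------------------------
# genome simulation
# ---------------------------------------------------------------------------

POLX_LEVELS = ("none", "canonical", "altered", "both")
NHEJ_LEVELS = ("none", "nhej_nuc", "nhej_no_nuc")


def default_joint_probs() -> dict[tuple[str, str], float]:
    """Joint (polx_status, nhej_status) distribution approximating the
    published marginals: 72.8% / 20.6% / 6.6% of genomes without NHEJ, with
    the nuclease-bearing and with the nuclease-less pathway, and the
    per-group PolX conditionals (10.3%/3.0%, 7.7%/7.2%, 43%/5.9% canonical/
    altered respectively)."""
    nhej_marginals = {"none": 0.728, "nhej_nuc": 0.206, "nhej_no_nuc": 0.066}
    polx_given_nhej = {
        "none": {"canonical": 0.103, "altered": 0.030},
        "nhej_nuc": {"canonical": 0.077, "altered": 0.072},
        "nhej_no_nuc": {"canonical": 0.430, "altered": 0.059},
    }
    joint = {}
    for nhej, p_nhej in nhej_marginals.items():
        cond = polx_given_nhej[nhej]
        p_none = 1.0 - sum(cond.values())
        joint[("none", nhej)] = p_nhej * p_none
        joint[("canonical", nhej)] = p_nhej * cond["canonical"]
        joint[("altered", nhej)] = p_nhej * cond["altered"]
        joint[("both", nhej)] = 0.0
    total = sum(joint.values())
    return {k: v / total for k, v in joint.items()}


def independent_joint_probs(
    polx_marginals: dict[str, float], nhej_marginals: dict[str, float]
) -> dict[tuple[str, str], float]:
    """Product joint with independent margins (null for the chi-square test)."""
    return {
        (p, n): pp * pn
        for p, pp in polx_marginals.items()
        for n, pn in nhej_marginals.items()
    }


def draw_statuses(
    n: int, joint_probs: dict[tuple[str, str], float], rng: np.random.Generator
) -> list[tuple[str, str]]:
    """Draw n (polx_status, nhej_status) pairs from a joint distribution."""
    keys = sorted(joint_probs)
    probs = np.array([joint_probs[k] for k in keys], dtype=float)
    if (probs < 0).any() or abs(probs.sum() - 1.0) > 1e-9:
        raise ValueError("joint_probs must be a valid probability distribution")
    idx = rng.choice(len(keys), size=n, p=probs)
    return [keys[i] for i in idx]


@dataclass(frozen=True)
class GenomeTruth:
    joint_probs: dict[tuple[str, str], float]
    seed: int
    partner_family: str
    rows: dict[str, dict]  # genome_id -> planted facts


TAXON_CLASSES = ("ClassAlpha", "ClassBeta", "ClassGamma", "ClassDelta")
TAXON_PHYLA = ("PhylumOne", "PhylumTwo")

_DECOYS = ("ku_only", "lig_only", "split_ligd", "ku_plus_split")


def simulate_genomes(
    n_genomes: int,
    joint_probs: dict[tuple[str, str], float] | None = None,
    genes_per_genome_range: tuple[int, int] = (20, 50),
    mean_intergenic_gap: int = 120,
    max_intergenic_gap: int = 1000,
    planted_partner_family: str = "PF_PARTNER",
    partner_probability: float = 0.0,
    decoy_probability: float = 0.2,
    nhej_length_shift: int = 0,
    seed: int = 0,
) -> tuple[list[GeneRecord], GenomeTruth]:
    """Simulate annotated gene tables for ``n_genomes`` linear replicons.

    Each genome draws a (polx_status, nhej_status) pair from ``joint_probs``
    and realizes it exactly through role labels; NHEJ-less genomes may carry
    non-qualifying decoy architectures (Ku alone, ligase alone, split
    ligase/polymerase proteins).  With ``partner_probability`` a PolX gene
    gets an adjacent co-directional gene of ``planted_partner_family``
    within 300 bp.  ``nhej_length_shift`` adds the given bp to the planted
    genome length of NHEJ-positive genomes.
    """
    if n_genomes < 1:
        raise ValueError("n_genomes must be >= 1")
    joint_probs = joint_probs if joint_probs is not None else default_joint_probs()
    lo, hi = genes_per_genome_range
    if lo < 8:
        raise ValueError("genomes need at least 8 genes to place all roles")

    rng = np.random.default_rng(seed)
    statuses = draw_statuses(n_genomes, joint_probs, rng)

    genes: list[GeneRecord] = []
    rows: dict[str, dict] = {}
    background_families = [f"PF{i:05d}" for i in range(50)]

    for gi in range(n_genomes):
        genome_id = f"G{gi:05d}"
        replicon_id = f"{genome_id}_r1"
        polx_status, nhej_status = statuses[gi]
        taxon_class = TAXON_CLASSES[int(rng.integers(0, len(TAXON_CLASSES)))]
        taxon_phylum = TAXON_PHYLA[int(rng.integers(0, len(TAXON_PHYLA)))]

        n_genes = int(rng.integers(lo, hi + 1))
        lengths = rng.integers(300, 3000, size=n_genes)
        gaps = np.minimum(
            rng.geometric(1.0 / mean_intergenic_gap, size=n_genes), max_intergenic_gap
        )
        strands = np.where(rng.random(n_genes) < 0.5, "+", "-")

        # role placement on distinct genes
        n_polx = {"none": 0, "canonical": 1, "altered": 1, "both": 2}[polx_status]
        n_special = n_polx + 4  # head-room for NHEJ genes and decoys
        special = rng.choice(n_genes, size=n_special, replace=False)
        cursor = 0
        roles: dict[int, frozenset[str]] = {}
        polx_indices: list[int] = []
        if polx_status in ("canonical", "both"):
            polx_indices.append(int(special[cursor]))
            roles[int(special[cursor])] = frozenset({"POLX_CANONICAL"})
            cursor += 1
        if polx_status in ("altered", "both"):
            polx_indices.append(int(special[cursor]))
            roles[int(special[cursor])] = frozenset({"POLX_ALTERED"})
            cursor += 1
        if nhej_status == "nhej_nuc":
            roles[int(special[cursor])] = frozenset({"KU"})
            roles[int(special[cursor + 1])] = frozenset({"LIG", "POL_DOM", "PE"})
            cursor += 2
        elif nhej_status == "nhej_no_nuc":
            roles[int(special[cursor])] = frozenset({"KU"})
            roles[int(special[cursor + 1])] = frozenset({"LIG", "POL_DOM"})
            cursor += 2
        else:
            if rng.random() < decoy_probability:
                decoy = _DECOYS[int(rng.integers(0, len(_DECOYS)))]
                if decoy == "ku_only":
                    roles[int(special[cursor])] = frozenset({"KU"})
                elif decoy == "lig_only":
                    roles[int(special[cursor])] = frozenset({"LIG"})
                elif decoy == "split_ligd":
                    roles[int(special[cursor])] = frozenset({"LIG"})
                    roles[int(special[cursor + 1])] = frozenset({"POL_DOM"})
                else:  # ku_plus_split
                    roles[int(special[cursor])] = frozenset({"KU"})
                    roles[int(special[cursor + 1])] = frozenset({"LIG"})
                    roles[int(special[cursor + 2])] = frozenset({"POL_DOM"})
                cursor += 3

        special_set = set(roles)

        # background Pfam families on non-special genes
        fams: dict[int, frozenset[str]] = {}
        for j in range(n_genes):
            if j not in special_set and rng.random() < 0.3:
                fams[j] = frozenset(
                    {background_families[int(rng.integers(0, len(background_families)))]}
                )

        # planted operon partner next to a PolX gene
        partner_planted = False
        if polx_indices and rng.random() < partner_probability:
            focal = polx_indices[0]
            for neighbor in (focal + 1, focal - 1):
                if 0 <= neighbor < n_genes and neighbor not in special_set:
                    fams[neighbor] = frozenset({planted_partner_family})
                    strands[neighbor] = strands[focal]
                    right = max(focal, neighbor)
                    gaps[right] = int(rng.integers(0, 301))
                    partner_planted = True
                    break

        # realize coordinates
        pos = 0
        for j in range(n_genes):
            start = pos + int(gaps[j]) + 1
            end = start + int(lengths[j]) - 1
            pos = end
            genes.append(
                GeneRecord(
                    genome_id=genome_id,
                    replicon_id=replicon_id,
                    start=start,
                    end=end,
                    strand=str(strands[j]),
                    protein_id=f"{genome_id}_p{j:03d}",
                    roles=roles.get(j, frozenset()),
                    pfam_families=fams.get(j, frozenset()),
                    taxon_class=taxon_class,
                    taxon_phylum=taxon_phylum,
                )
            )

        genome_length = pos + int(rng.integers(100, 5000))
        if nhej_status != "none":
            genome_length += nhej_length_shift
        rows[genome_id] = {
            "polx_status": polx_status,
            "nhej_status": nhej_status,
            "n_polx_genes": n_polx,
            "partner_planted": partner_planted,
            "genome_length": genome_length,
            "taxon_class": taxon_class,
            "taxon_phylum": taxon_phylum,
        }

    truth = GenomeTruth(
        joint_probs=dict(joint_probs),
        seed=seed,
        partner_family=planted_partner_family,
        rows=rows,
    )
    return genes, truth
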
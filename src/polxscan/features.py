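"""Per-sequence feature calls on an anchored PolX alignment.

Three families of features are extracted, all phrased in reference residue
numbering and resolved to alignment columns through a
:class:`~polxscan.alignment.ReferenceAnchor`:

* catalytic-triad classification (canonical / altered / indeterminate),
* palm and fingers window lengths with truncation flags,
* residue states at named active-site positions (dNTP-binding residues,
  steric gate, GS motif, nine-residue nuclease-domain consensus).
"""

from __future__ import annotations

import statistics
from collections import Counter
from dataclasses import dataclass, field

from .alignment import GAP, Msa, ReferenceAnchor, columns_for_range, ungapped_length

ACIDIC = {"D", "E"}
INDETERMINATE_CHARS = {GAP, "X"}

CLASS_CANONICAL = "canonical"
CLASS_ALTERED = "altered"
CLASS_INDETERMINATE = "indeterminate"

# Catalytic aspartates of human DNA polymerase beta (UniProt P06746,
# numbering from Met1): D190, D192, D256.  Configurable, not hard-coded
# downstream; this is only the shipped default.
DEFAULT_TRIAD_RESIDUES = (190, 192, 256)


@dataclass(frozen=True)
class TriadSpec:
    """The three catalytic acidic positions, in reference numbering."""

    reference_id: str
    residue_numbers: tuple[int, int, int] = DEFAULT_TRIAD_RESIDUES

    def __post_init__(self):
        a, b, c = self.residue_numbers
        if not (a < b < c):
            raise ValueError("triad residue numbers must be strictly increasing")


@dataclass(frozen=True)
class TriadCall:
    seq_id: str
    triad: str
    triad_class: str


def classify_triad(triad: str) -> str:
    """Classify a 3-character triad string.

    canonical iff all three characters are acidic (D/E); otherwise
    indeterminate if any character is a gap or 'X'; otherwise altered.
    """
    if all(ch in ACIDIC for ch in triad):
        return CLASS_CANONICAL
    if any(ch in INDETERMINATE_CHARS for ch in triad):
        return CLASS_INDETERMINATE
    return CLASS_ALTERED


def call_triads(msa: Msa, anchor: ReferenceAnchor, spec: TriadSpec) -> list[TriadCall]:
    """One :class:`TriadCall` per sequence, in alignment order."""
    cols = [anchor.column(r) for r in spec.residue_numbers]
    calls = []
    for seq_id, seq in msa.records:
        triad = "".join(seq[c] for c in cols)
        calls.append(TriadCall(seq_id=seq_id, triad=triad, triad_class=classify_triad(triad)))
    return calls


def triad_variant_census(calls: list[TriadCall]) -> list[tuple[str, int]]:
    """Distinct triad strings among altered calls, sorted by descending
    count, ties broken lexicographically."""
    counter = Counter(c.triad for c in calls if c.triad_class == CLASS_ALTERED)
    return sorted(counter.items(), key=lambda kv: (-kv[1], kv[0]))


@dataclass(frozen=True)
class DomainWindows:
    """Palm/fingers windows (reference numbering, inclusive) and the strict
    truncation thresholds applied to their non-gap lengths."""

    palm: tuple[int, int] = (178, 279)
    fingers: tuple[int, int] = (272, 314)
    palm_truncation_threshold: int = 77
    fingers_truncation_threshold: int = 55

    def __post_init__(self):
        if self.palm_truncation_threshold <= 0 or self.fingers_truncation_threshold <= 0:
            raise ValueError("truncation thresholds must be positive")
        for lo, hi in (self.palm, self.fingers):
            if lo > hi:
                raise ValueError("window start must not exceed window end")


@dataclass(frozen=True)
class DomainMetrics:
    seq_id: str
    full_length: int
    palm_length: int
    fingers_length: int
    palm_truncated: bool
    fingers_truncated: bool
    double_truncated: bool


def window_length(seq: str, anchor: ReferenceAnchor, window: tuple[int, int]) -> int:
    """Non-gap residues of ``seq`` within the inclusive column interval of a
    reference window.  Insertion columns inside the interval count, so
    subject insertions lengthen the measured domain."""
    c0, c1 = columns_for_range(anchor, *window)
    return ungapped_length(seq[c0 : c1 + 1])


def measure_domains(
    msa: Msa, anchor: ReferenceAnchor, windows: DomainWindows | None = None
) -> list[DomainMetrics]:
    windows = windows or DomainWindows()
    out = []
    for seq_id, seq in msa.records:
        palm_len = window_length(seq, anchor, windows.palm)
        fingers_len = window_length(seq, anchor, windows.fingers)
        palm_trunc = palm_len < windows.palm_truncation_threshold
        fingers_trunc = fingers_len < windows.fingers_truncation_threshold
        out.append(
            DomainMetrics(
                seq_id=seq_id,
                full_length=ungapped_length(seq),
                palm_length=palm_len,
                fingers_length=fingers_len,
                palm_truncated=palm_trunc,
                fingers_truncated=fingers_trunc,
                double_truncated=palm_trunc and fingers_trunc,
            )
        )
    return out


@dataclass(frozen=True)
class SiteSpec:
    """Named sites in reference numbering.

    Each site is a tuple of reference residue numbers; a state string is
    read from exactly those residue columns (insertion columns between them
    are ignored).  Defaults follow human Pol-beta numbering.
    """

    sites: dict[str, tuple[int, ...]] = field(
        default_factory=lambda: {
            "dntp_basic": (276,),
            "dntp_N": (279,),
            "steric_gate": (271, 272),
            "gs_motif": (274, 275),
            "palm_R": (183,),
        }
    )

    def with_php_site(self, positions: tuple[int, ...]) -> "SiteSpec":
        sites = dict(self.sites)
        sites["php_site"] = tuple(positions)
        return SiteSpec(sites=sites)


@dataclass(frozen=True)
class MotifProfile:
    seq_id: str
    states: dict[str, str]


def profile_motifs(msa: Msa, anchor: ReferenceAnchor, sites: SiteSpec | None = None) -> list[MotifProfile]:
    """Per-sequence residue states at each named site.

    Only the columns of the listed reference residues are read, so each
    state string has exactly the site's width.
    """
    sites = sites or SiteSpec()
    site_cols = {
        name: [anchor.column(r) for r in residues] for name, residues in sites.sites.items()
    }
    profiles = []
    for seq_id, seq in msa.records:
        states = {name: "".join(seq[c] for c in cols) for name, cols in site_cols.items()}
        profiles.append(MotifProfile(seq_id=seq_id, states=states))
    return profiles


def _length_summary(values: list[int]) -> dict:
    n = len(values)
    if n == 0:
        return {"n": 0, "mean": None, "median": None, "ci95_low": None, "ci95_high": None}
    mean = statistics.fmean(values)
    median = statistics.median(values)
    if n > 1:
        sd = statistics.stdev(values)
        half = 1.96 * sd / n**0.5
    else:
        half = 0.0
    return {
        "n": n,
        "mean": mean,
        "median": median,
        "ci95_low": mean - half,
        "ci95_high": mean + half,
    }


def summarize_conservation(
    calls: list[TriadCall],
    profiles: list[MotifProfile],
    metrics: list[DomainMetrics],
) -> dict:
    """Per-class site-state frequencies and length summaries.

    For every site and every triad class the report gives, for each observed
    state string, its percentage among the class members (states containing
    gaps or 'X' are reported like any other state and stay in the
    denominator).  Length summaries give n, mean, median and a 95% normal
    CI of the mean for full/palm/fingers lengths per class.
    """
    class_by_id = {c.seq_id: c.triad_class for c in calls}
    if not (set(class_by_id) == {p.seq_id for p in profiles} == {m.seq_id for m in metrics}):
        raise ValueError("calls, profiles and metrics must share seq_ids")

    classes = (CLASS_CANONICAL, CLASS_ALTERED, CLASS_INDETERMINATE)
    site_names = list(profiles[0].states) if profiles else []

    site_report: dict[str, dict[str, dict]] = {}
    for site in site_names:
        per_class = {}
        for cls in classes:
            states = [p.states[site] for p in profiles if class_by_id[p.seq_id] == cls]
            n = len(states)
            counter = Counter(states)
            per_class[cls] = {
                "n": n,
                "state_percent": (
                    {s: 100.0 * k / n for s, k in sorted(counter.items(), key=lambda kv: (-kv[1], kv[0]))}
                    if n
                    else {}
                ),
            }
        site_report[site] = per_class

    length_report = {}
    for cls in classes:
        ids = {sid for sid, c in class_by_id.items() if c == cls}
        cls_metrics = [m for m in metrics if m.seq_id in ids]
        length_report[cls] = {
            "full_length": _length_summary([m.full_length for m in cls_metrics]),
            "palm_length": _length_summary([m.palm_length for m in cls_metrics]),
            "fingers_length": _length_summary([m.fingers_length for m in cls_metrics]),
        }

    return {"sites": site_report, "lengths": length_report}
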
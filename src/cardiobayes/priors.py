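"""Gene-level prior odds of pathogenicity from case/control burden tables.

The prior odds that a rare variant found in an affected referral is
pathogenic are estimated per gene, syndrome and variant-class group
(radical vs non-radical) from the proportion of individuals carrying a
rare variant of that type in cases versus population controls:

    prior odds = (case burden - control burden) / control burden

with three adjustment policies:

* a zero (or missing) control burden is replaced by the minimum non-zero
  frequency 0.0002 before the ratio is taken;
* for LQTS genes, burdens from a prospective clinical case series are
  preferred where available; literature-derived odds are halved (clinical
  referral yields run about half the research-literature yields), and any
  prior odds below 0.2 are floored at 0.2 (burden estimates are too noisy
  in that range);
* for HCM and BrS genes only literature case burdens exist and control
  burdens are unstable, so a fixed average benign burden of 1% is used,
  i.e. prior odds = case burden / 0.01.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

CLASS_GROUPS = ("non_radical", "radical")
SOURCES = ("case_series", "literature")

#: Control burden substituted for a zero/missing estimate (one carrier
#: among ~5,000 individuals).
MIN_NONZERO_FREQUENCY = 0.0002

#: Floor applied to LQTS prior odds.
LQTS_TRUNCATION = 0.2

#: Assumed average benign rare-variant burden for HCM and BrS genes.
FIXED_CONTROL_BURDEN = 0.01


class BurdenTableError(ValueError):
    pass


@dataclass(frozen=True)
class BurdenRow:
    gene: str
    syndrome: str
    class_group: str
    case_burden: float
    control_burden: float | None
    source: str

    def __post_init__(self) -> None:
        if self.class_group not in CLASS_GROUPS:
            raise BurdenTableError(f"unknown class_group {self.class_group!r}")
        if self.source not in SOURCES:
            raise BurdenTableError(f"unknown source {self.source!r}")
        for name in ("case_burden", "control_burden"):
            v = getattr(self, name)
            if v is not None and not 0.0 <= v <= 1.0:
                raise BurdenTableError(
                    f"{self.gene}/{self.syndrome}/{self.class_group}: "
                    f"{name}={v} outside [0, 1]"
                )


@dataclass
class BurdenTable:
    """Per gene x syndrome x class-group rare-variant carrier proportions."""

    rows: list[BurdenRow] = field(default_factory=list)

    def __post_init__(self) -> None:
        seen: dict[tuple, BurdenRow] = {}
        dupes = []
        for row in self.rows:
            key = (row.gene, row.syndrome, row.class_group, row.source)
            if key in seen and seen[key] != row:
                dupes.append(key)
            seen[key] = row
        if dupes:
            raise BurdenTableError(f"conflicting duplicate burden rows: {sorted(dupes)}")

    def select(self, gene: str, syndrome: str, class_group: str) -> list[BurdenRow]:
        return [
            r
            for r in self.rows
            if (r.gene, r.syndrome, r.class_group) == (gene, syndrome, class_group)
        ]


@dataclass
class PriorPolicyConfig:
    """Tunable policy constants, defaulting to the published values."""

    min_nonzero_frequency: float = MIN_NONZERO_FREQUENCY
    lqts_truncation: float = LQTS_TRUNCATION
    fixed_control_burden: float = FIXED_CONTROL_BURDEN
    literature_reduction: float = 2.0


@dataclass(frozen=True)
class PriorOddsEntry:
    gene: str
    syndrome: str
    class_group: str
    prior_odds: float
    policy: str


@dataclass
class PriorOddsTable:
    """Gene-level prior odds per syndrome and class group, with provenance."""

    entries: dict[tuple[str, str, str], PriorOddsEntry] = field(default_factory=dict)

    def add(self, entry: PriorOddsEntry) -> None:
        self.entries[(entry.gene, entry.syndrome, entry.class_group)] = entry

    def lookup(self, gene: str, syndrome: str, class_group: str) -> float:
        key = (gene, syndrome, class_group)
        if key not in self.entries:
            raise KeyError(
                f"no prior odds for gene {gene!r} ({syndrome}, {class_group}); "
                "extend the burden table to cover this gene"
            )
        return self.entries[key].prior_odds

    def genes(self, syndrome: str | None = None) -> list[str]:
        names = {
            g for (g, s, _c) in self.entries if syndrome is None or s == syndrome
        }
        return sorted(names)

    def __len__(self) -> int:
        return len(self.entries)


def subtractive_prior_odds(
    case_burden: float,
    control_burden: float | None,
    *,
    min_nonzero_frequency: float = MIN_NONZERO_FREQUENCY,
) -> float:
    """(case - control) / control with zero-replacement of the control burden.

    A zero or missing control burden is replaced by
    ``min_nonzero_frequency`` (a single observed carrier) before the ratio
    is evaluated.  No truncation is applied here; the result is negative
    when controls carry more rare variants than cases, and downstream
    policies (the LQTS floor) restore positivity.
    """
    if case_burden < 0:
        raise ValueError("case_burden must be non-negative")
    if control_burden is not None and control_burden < 0:
        raise ValueError("control_burden must be non-negative")
    if not control_burden:  # 0 or None
        control_burden = min_nonzero_frequency
    return (case_burden - control_burden) / control_burden


def lqts_policy(
    raw_odds: float,
    source: str,
    *,
    truncation: float = LQTS_TRUNCATION,
    literature_reduction: float = 2.0,
) -> float:
    """Apply the LQTS adjustments: halve literature-derived odds, then floor.

    Case-series odds are floored but not halved.
    """
    if source not in SOURCES:
        raise BurdenTableError(f"unknown source {source!r}")
    odds = raw_odds / literature_reduction if source == "literature" else raw_odds
    return max(odds, truncation)


def fixed_control_prior_odds(
    case_burden: float, *, control_burden: float = FIXED_CONTROL_BURDEN
) -> float:
    """HCM/BrS policy: case burden over a fixed 1% benign burden."""
    if case_burden < 0:
        raise ValueError("case_burden must be non-negative")
    return case_burden / control_burden


def build_prior_table(
    burdens: BurdenTable, config: PriorPolicyConfig | None = None
) -> PriorOddsTable:
    """Compute the full prior-odds table under the per-syndrome policies.

    LQTS: the case-series row is preferred when present; the subtractive
    formula is applied, then literature halving and the 0.2 floor.
    HCM/BrS: the literature case burden over the fixed 1% control burden,
    identically for both class groups.  Every entry records the policy
    that produced it.
    """
    config = config or PriorPolicyConfig()
    table = PriorOddsTable()
    keys = sorted({(r.gene, r.syndrome, r.class_group) for r in burdens.rows})
    for gene, syndrome, class_group in keys:
        rows = burdens.select(gene, syndrome, class_group)
        by_source = {r.source: r for r in rows}
        if syndrome == "LQTS":
            source = "case_series" if "case_series" in by_source else "literature"
            row = by_source[source]
            raw = subtractive_prior_odds(
                row.case_burden,
                row.control_burden,
                min_nonzero_frequency=config.min_nonzero_frequency,
            )
            odds = lqts_policy(
                raw,
                source,
                truncation=config.lqts_truncation,
                literature_reduction=config.literature_reduction,
            )
            policy = f"subtractive:{source}" + (
                ":halved" if source == "literature" else ""
            ) + (":floored" if odds != (raw if source == "case_series" else raw / config.literature_reduction) else "")
        else:
            row = by_source.get("literature") or rows[0]
            odds = fixed_control_prior_odds(
                row.case_burden, control_burden=config.fixed_control_burden
            )
            policy = f"fixed_control:{config.fixed_control_burden}"
        table.add(
            PriorOddsEntry(
                gene=gene,
                syndrome=syndrome,
                class_group=class_group,
                prior_odds=odds,
                policy=policy,
            )
        )
    return table
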
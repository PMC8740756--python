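"""Nuclear capture analyses: molecular sex and faunal mis-mapping.

Sex is estimated from the fraction of deaminated fragments hitting
X-chromosome target sites versus autosomal ones. With Sx X sites and Sa
autosomal sites on the capture panel, the expected X fraction is
Sx/(Sx + 2·Sa) for a male (one X copy against two of each autosome) and
Sx·2/(Sx·2 + 2·Sa) = Sx/(Sx + Sa) for a female. The observed fraction
gets a Wilson 95% CI; the call requires the CI to separate the two
expectations. Capture efficiency is assumed equal for X and autosomal
probes.

Faunal mis-mapping — non-hominin fragments aligning to the hominin
reference — is estimated from hominin-diagnostic alleles: the fraction of
fragments carrying the faunal state, screened at the 2% bar.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal, Mapping, Sequence

import pandas as pd

from sedadna.damage import (
    AncientOriginVerdict,
    ancient_origin_test,
    binomial_ci,
    terminal_profile,
)
from sedadna.types import AlignedFragment


@dataclass(frozen=True)
class NuclearSite:
    chromosome: str           # "X" or an autosome label
    position: int
    hominin_allele: str
    faunal_allele: str

    def __post_init__(self) -> None:
        if self.hominin_allele == self.faunal_allele:
            raise ValueError(f"site {self.chromosome}:{self.position} "
                             "alleles must differ")

    @property
    def is_x(self) -> bool:
        return self.chromosome == "X"


@dataclass
class NuclearSitePanel:
    sites: list[NuclearSite]

    def __post_init__(self) -> None:
        if not self.sites:
            raise ValueError("site panel must contain at least one site")

    @property
    def n_x_sites(self) -> int:
        return sum(s.is_x for s in self.sites)

    @property
    def n_auto_sites(self) -> int:
        return len(self.sites) - self.n_x_sites

    def expected_x_fraction(self, sex: Literal["male", "female"]) -> float:
        sx, sa = self.n_x_sites, self.n_auto_sites
        cx = 1 if sex == "male" else 2
        return sx * cx / (sx * cx + 2 * sa)

    def site_at(self, chromosome: str, position: int) -> NuclearSite | None:
        for s in self.sites:
            if s.chromosome == chromosome and s.position == position:
                return s
        return None

    def to_tsv(self, path: str | Path) -> None:
        pd.DataFrame(
            [
                {"chromosome": s.chromosome, "position": s.position,
                 "hominin_allele": s.hominin_allele,
                 "faunal_allele": s.faunal_allele}
                for s in self.sites
            ]
        ).to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path: str | Path) -> "NuclearSitePanel":
        df = pd.read_csv(path, sep="\t")
        return cls([
            NuclearSite(str(r.chromosome), int(r.position),
                        str(r.hominin_allele), str(r.faunal_allele))
            for r in df.itertuples()
        ])


@dataclass(frozen=True)
class NuclearFragment:
    """A deaminated fragment reduced to its informative site overlap."""

    fragment_id: str
    chromosome: str
    position: int
    allele: str
    deaminated: bool = True

    @property
    def is_x(self) -> bool:
        return self.chromosome == "X"


@dataclass
class SexEstimate:
    n_x: int
    n_auto: int
    x_fraction: float
    ci: tuple[float, float]
    expected_male: float
    expected_female: float
    call: Literal["male", "female", "undetermined"]


def estimate_sex(
    fragments: Sequence[NuclearFragment],
    panel: NuclearSitePanel,
    deaminated_only: bool = True,
) -> SexEstimate:
    """Sex call from the X fraction of deaminated fragments at panel sites.

    Wilson 95% CI against the two copy-number expectations:
    - CI contains exactly one expectation → that sex;
    - CI contains both → undetermined (insufficient data);
    - CI excludes both → the expectation nearer the point estimate
      (a fraction below the male expectation is still male, above the
      female expectation still female; a large, precise sample lands a
      hair outside its own expectation about 5% of the time and must not
      be discarded for it).
    """
    informative = [
        f for f in fragments if f.deaminated or not deaminated_only
    ]
    n_x = sum(f.is_x for f in informative)
    n_auto = len(informative) - n_x
    if n_x + n_auto == 0:
        raise ValueError("no informative fragments")
    exp_m = panel.expected_x_fraction("male")
    exp_f = panel.expected_x_fraction("female")
    frac = n_x / (n_x + n_auto)
    lo, hi = binomial_ci(n_x, n_x + n_auto)
    contains_m = lo <= exp_m <= hi
    contains_f = lo <= exp_f <= hi
    if contains_m and not contains_f:
        call = "male"
    elif contains_f and not contains_m:
        call = "female"
    elif contains_m and contains_f:
        call = "undetermined"
    else:  # excludes both: nearest expectation
        call = "male" if abs(frac - exp_m) <= abs(frac - exp_f) else "female"
    return SexEstimate(
        n_x=n_x, n_auto=n_auto, x_fraction=frac, ci=(lo, hi),
        expected_male=exp_m, expected_female=exp_f, call=call,
    )


@dataclass
class MismappingEstimate:
    n_faunal: int
    n_total: int
    proportion: float
    ci: tuple[float, float]
    threshold: float
    passes: bool   # strictly below the threshold on the point estimate


def faunal_mismapping(
    fragments: Sequence[NuclearFragment],
    panel: NuclearSitePanel,
    threshold: float = 0.02,
) -> MismappingEstimate:
    """Fraction of fragments carrying the faunal allele at diagnostic sites.

    The screening criterion is strict: a point estimate of exactly 2% does
    not pass the "less than 2%" bar. Fragments whose allele matches
    neither state are ignored.
    """
    n_faunal = 0
    n_total = 0
    for f in fragments:
        site = panel.site_at(f.chromosome, f.position)
        if site is None:
            continue
        if f.allele == site.faunal_allele:
            n_faunal += 1
            n_total += 1
        elif f.allele == site.hominin_allele:
            n_total += 1
    if n_total == 0:
        raise ValueError("no fragments overlap diagnostic sites")
    prop = n_faunal / n_total
    return MismappingEstimate(
        n_faunal=n_faunal,
        n_total=n_total,
        proportion=prop,
        ci=binomial_ci(n_faunal, n_total),
        threshold=threshold,
        passes=prop < threshold,
    )


def damage_screen(
    libraries: Mapping[str, Sequence[AlignedFragment]],
    sample_of: Mapping[str, str] | None = None,
    threshold: float = 0.10,
) -> tuple[dict[str, AncientOriginVerdict], dict[str, list[AlignedFragment]]]:
    """Screen libraries for damage and merge same-sample libraries.

    Each library gets the two-ended terminal C→T test; libraries belonging
    to the same sample (``sample_of``: library → sample, identity by
    default) are merged afterwards, a merged sample inheriting the union
    of fragments of its libraries that passed the screen.
    """
    verdicts = {}
    for lib_id, frags in sorted(libraries.items()):
        verdicts[lib_id] = ancient_origin_test(
            terminal_profile(frags, "5p", 1),
            terminal_profile(frags, "3p", 1),
            threshold=threshold,
        )
    merged: dict[str, list[AlignedFragment]] = {}
    for lib_id, frags in sorted(libraries.items()):
        if not verdicts[lib_id].is_ancient:
            continue
        sample = (sample_of or {}).get(lib_id, lib_id)
        merged.setdefault(sample, []).extend(frags)
    return verdicts, merged


def sex_summary_frame(estimates: Mapping[str, SexEstimate]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {"sample": s, "n_X": e.n_x, "n_auto": e.n_auto,
             "x_fraction": e.x_fraction, "ci_low": e.ci[0],
             "ci_high": e.ci[1], "expected_male": e.expected_male,
             "expected_female": e.expected_female, "call": e.call}
            for s, e in sorted(estimates.items())
        ]
    )
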
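"""Domain types for two-arm trials, meta-analyses and trial networks.

The unit of analysis is a single randomized two-arm comparison summarized
either by a 2x2 table (binary outcome), by per-arm means/SDs (continuous
outcome), or by a generic effect size with its standard error (the form in
which published case-study data such as standardized mean differences from
regulatory reviews usually arrive).  Trials sharing one treatment comparison
form a meta-analysis; a collection of such meta-analyses forms a network.

A flat CSV exchange format covers all three variants: one row per trial with
columns ``comparison, trial_id, variant, x_E, n_E, x_C, n_C, m_E, s_E, m_C,
s_C, estimate, se, scale`` (unused columns left empty).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Union

import pandas as pd

__all__ = [
    "TwoArmBinaryTrial",
    "TwoArmContinuousTrial",
    "GenericEffectTrial",
    "Trial",
    "MetaAnalysisData",
    "TrialNetwork",
    "ValidationError",
    "SchemaError",
    "read_network",
    "write_network",
    "effect_vector_fixtures",
    "worked_example_counts",
    "OEFixture",
]

CSV_COLUMNS = [
    "comparison", "trial_id", "variant",
    "x_E", "n_E", "x_C", "n_C",
    "m_E", "s_E", "m_C", "s_C",
    "estimate", "se", "scale",
]


class ValidationError(ValueError):
    """A trial row violates a domain invariant (negative count, x > n, ...)."""


class SchemaError(ValueError):
    """The file cannot be mapped onto the trial schema."""


@dataclass(frozen=True)
class TwoArmBinaryTrial:
    """Events/sample sizes of a two-arm trial with a binary outcome."""

    x_E: int
    n_E: int
    x_C: int
    n_C: int
    trial_id: str = ""

    def __post_init__(self) -> None:
        for name in ("x_E", "n_E", "x_C", "n_C"):
            v = getattr(self, name)
            if not isinstance(v, (int,)) or isinstance(v, bool):
                raise ValidationError(f"{name} must be an integer, got {v!r}")
        if self.n_E < 1 or self.n_C < 1:
            raise ValidationError(
                f"arm sizes must be >= 1 (n_E={self.n_E}, n_C={self.n_C})")
        if not (0 <= self.x_E <= self.n_E):
            raise ValidationError(
                f"need 0 <= x_E <= n_E, got x_E={self.x_E}, n_E={self.n_E}")
        if not (0 <= self.x_C <= self.n_C):
            raise ValidationError(
                f"need 0 <= x_C <= n_C, got x_C={self.x_C}, n_C={self.n_C}")

    @property
    def total_n(self) -> int:
        return self.n_E + self.n_C


@dataclass(frozen=True)
class TwoArmContinuousTrial:
    """Per-arm mean/SD/size of a two-arm trial with a continuous outcome."""

    m_E: float
    s_E: float
    n_E: int
    m_C: float
    s_C: float
    n_C: int
    trial_id: str = ""

    def __post_init__(self) -> None:
        if self.s_E <= 0 or self.s_C <= 0:
            raise ValidationError(
                f"SDs must be positive (s_E={self.s_E}, s_C={self.s_C})")
        if self.n_E < 2 or self.n_C < 2:
            raise ValidationError(
                f"arm sizes must be >= 2 (n_E={self.n_E}, n_C={self.n_C})")
        for name in ("m_E", "s_E", "m_C", "s_C"):
            if not math.isfinite(getattr(self, name)):
                raise ValidationError(f"{name} must be finite")

    @property
    def total_n(self) -> int:
        return self.n_E + self.n_C


ALLOWED_SCALES = ("log_or", "smd")


@dataclass(frozen=True)
class GenericEffectTrial:
    """A trial known only through an effect estimate and its standard error.

    ``scale_tag`` records the analysis scale: ``log_or`` for log odds ratios,
    ``smd`` for standardized mean differences.
    """

    estimate: float
    se: float
    scale_tag: str = "smd"
    trial_id: str = ""

    def __post_init__(self) -> None:
        if not (self.se > 0 and math.isfinite(self.se)):
            raise ValidationError(f"se must be positive and finite, got {self.se}")
        if not math.isfinite(self.estimate):
            raise ValidationError("estimate must be finite")
        if self.scale_tag not in ALLOWED_SCALES:
            raise ValidationError(
                f"scale_tag must be one of {ALLOWED_SCALES}, got {self.scale_tag!r}")

    @property
    def total_n(self) -> int:
        # Size is unknown; precision stands in for it when ranking trials.
        return 0


Trial = Union[TwoArmBinaryTrial, TwoArmContinuousTrial, GenericEffectTrial]

_VARIANT_NAMES = {
    TwoArmBinaryTrial: "binary",
    TwoArmContinuousTrial: "continuous",
    GenericEffectTrial: "generic",
}


@dataclass(frozen=True)
class MetaAnalysisData:
    """An ordered, variant-homogeneous set of trials of one comparison."""

    comparison: tuple[str, str]
    trials: tuple[Trial, ...]

    def __post_init__(self) -> None:
        if len(self.trials) == 0:
            raise ValidationError(
                f"meta-analysis {self.comparison} has no trials")
        kinds = {type(t) for t in self.trials}
        if len(kinds) != 1:
            raise SchemaError(
                f"comparison {self.comparison} mixes trial variants: "
                f"{sorted(_VARIANT_NAMES[k] for k in kinds)}")
        scales = {t.scale_tag for t in self.trials
                  if isinstance(t, GenericEffectTrial)}
        if len(scales) > 1:
            raise SchemaError(
                f"comparison {self.comparison} mixes effect scales: {sorted(scales)}")

    @property
    def n_j(self) -> int:
        return len(self.trials)

    @property
    def variant(self) -> str:
        return _VARIANT_NAMES[type(self.trials[0])]


@dataclass(frozen=True)
class TrialNetwork:
    """J meta-analyses with distinct treatment-comparison labels."""

    meta_analyses: tuple[MetaAnalysisData, ...]

    def __post_init__(self) -> None:
        if len(self.meta_analyses) == 0:
            raise ValidationError("network has no meta-analyses")
        labels = [ma.comparison for ma in self.meta_analyses]
        if len(set(labels)) != len(labels):
            raise ValidationError("comparison labels must be unique across the network")

    @property
    def J(self) -> int:
        return len(self.meta_analyses)

    @property
    def N(self) -> int:
        return sum(ma.n_j for ma in self.meta_analyses)


def _req(row: pd.Series, name: str, idx, kind=float):
    v = row.get(name)
    if v is None or (isinstance(v, float) and math.isnan(v)) or v == "":
        raise ValidationError(f"row {idx}: missing required field {name!r}")
    try:
        return kind(v)
    except (TypeError, ValueError) as exc:
        raise ValidationError(f"row {idx}: field {name!r} = {v!r} is not {kind.__name__}") from exc


def _int_field(row: pd.Series, name: str, idx) -> int:
    v = _req(row, name, idx, float)
    if v != int(v):
        raise ValidationError(f"row {idx}: field {name!r} = {v!r} is not an integer")
    return int(v)


def _row_to_trial(row: pd.Series, idx) -> Trial:
    variant = str(row.get("variant", "")).strip().lower()
    tid = str(row.get("trial_id", "") or "")
    try:
        if variant == "binary":
            return TwoArmBinaryTrial(
                x_E=_int_field(row, "x_E", idx), n_E=_int_field(row, "n_E", idx),
                x_C=_int_field(row, "x_C", idx), n_C=_int_field(row, "n_C", idx),
                trial_id=tid)
        if variant == "continuous":
            return TwoArmContinuousTrial(
                m_E=_req(row, "m_E", idx), s_E=_req(row, "s_E", idx),
                n_E=_int_field(row, "n_E", idx),
                m_C=_req(row, "m_C", idx), s_C=_req(row, "s_C", idx),
                n_C=_int_field(row, "n_C", idx), trial_id=tid)
        if variant == "generic":
            return GenericEffectTrial(
                estimate=_req(row, "estimate", idx), se=_req(row, "se", idx),
                scale_tag=str(row.get("scale", "") or "smd").strip(), trial_id=tid)
    except ValidationError as exc:
        raise ValidationError(f"row {idx}: {exc}") from exc
    raise SchemaError(f"row {idx}: unknown variant {variant!r} "
                      "(expected binary, continuous or generic)")


def _parse_comparison(label: str) -> tuple[str, str]:
    parts = [p.strip() for p in str(label).split(" vs ")]
    if len(parts) == 2:
        return (parts[0], parts[1])
    return (str(label), "")


def read_network(path, format_spec: dict[str, str] | None = None) -> TrialNetwork:
    """Read a :class:`TrialNetwork` from the flat CSV exchange format.

    Parameters
    ----------
    path
        CSV file with a mandatory header row.
    format_spec
        Optional mapping from schema column names to the file's column
        names, for files using different headers.
    """
    try:
        df = pd.read_csv(path, dtype={"comparison": str, "trial_id": str,
                                      "variant": str, "scale": str})
    except pd.errors.EmptyDataError as exc:
        raise SchemaError(f"{path}: empty file") from exc
    if format_spec:
        df = df.rename(columns={v: k for k, v in format_spec.items()})
    if "comparison" not in df.columns or "variant" not in df.columns:
        raise SchemaError(
            f"{path}: required columns 'comparison' and 'variant' not found "
            f"(have {list(df.columns)})")
    if len(df) == 0:
        raise SchemaError(f"{path}: no trial rows")
    mas = []
    # groupby(sort=False) preserves first-appearance order of comparisons
    # and row order within each comparison.
    for label, grp in df.groupby("comparison", sort=False):
        trials = tuple(_row_to_trial(row, idx) for idx, row in grp.iterrows())
        mas.append(MetaAnalysisData(comparison=_parse_comparison(label),
                                    trials=trials))
    return TrialNetwork(meta_analyses=tuple(mas))


def _trial_to_row(comparison: str, t: Trial) -> dict:
    row = {c: "" for c in CSV_COLUMNS}
    row["comparison"] = comparison
    row["trial_id"] = t.trial_id
    row["variant"] = _VARIANT_NAMES[type(t)]
    if isinstance(t, TwoArmBinaryTrial):
        row.update(x_E=t.x_E, n_E=t.n_E, x_C=t.x_C, n_C=t.n_C)
    elif isinstance(t, TwoArmContinuousTrial):
        row.update(m_E=t.m_E, s_E=t.s_E, n_E=t.n_E,
                   m_C=t.m_C, s_C=t.s_C, n_C=t.n_C)
    else:
        row.update(estimate=t.estimate, se=t.se, scale=t.scale_tag)
    return row


def write_network(net: TrialNetwork, path) -> None:
    """Write a network in the flat CSV exchange format (UTF-8, header row)."""
    rows = []
    for ma in net.meta_analyses:
        label = f"{ma.comparison[0]} vs {ma.comparison[1]}" if ma.comparison[1] \
            else ma.comparison[0]
        rows.extend(_trial_to_row(label, t) for t in ma.trials)
    pd.DataFrame(rows, columns=CSV_COLUMNS).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Printed fixtures: the true-effect vectors used to generate simulated
# networks, and the worked-example observed/expected counts.
# ---------------------------------------------------------------------------

#: True average odds ratios theta_j used for network generation, keyed by
#: (psi, nu, J): one frozen realization per hyper-parameter setting.  These
#: vectors were drawn once from log theta_j ~ Normal(psi, nu) and are reused
#: across scenarios; they are fixtures, not re-drawable.
_EFFECT_VECTORS: dict[tuple[float, float, int], tuple[float, ...]] = {
    (math.log(0.75), 0.02, 6): (0.793, 0.889, 0.741, 0.954, 0.569, 0.684),
    (math.log(0.75), 0.08, 6): (0.808, 0.725, 0.876, 0.698, 0.699, 0.395),
    (math.log(0.95), 0.02, 6): (0.796, 1.172, 1.000, 1.171, 1.099, 0.883),
    (math.log(0.95), 0.08, 6): (0.491, 1.214, 0.936, 0.977, 1.451, 0.754),
    (math.log(0.75), 0.02, 10): (0.658, 0.852, 0.696, 0.889, 0.741,
                                 0.722, 0.645, 0.683, 0.816, 0.796),
    (math.log(0.75), 0.08, 10): (0.978, 0.432, 1.149, 0.706, 0.432,
                                 0.751, 0.679, 0.653, 0.624, 0.568),
    (math.log(0.95), 0.02, 10): (1.081, 1.089, 0.767, 0.973, 0.781,
                                 0.763, 1.266, 0.816, 1.066, 0.992),
    (math.log(0.95), 0.08, 10): (0.845, 0.637, 1.030, 0.799, 0.541,
                                 0.851, 1.063, 1.307, 0.674, 0.732),
}


def effect_vector_fixtures() -> dict[tuple[float, float, int], tuple[float, ...]]:
    """Frozen true-effect (odds ratio) vectors for network simulation.

    Keys are ``(psi, nu, J)`` with psi the log-scale mean (log 0.75 or
    log 0.95), nu the log-scale variance (0.02 or 0.08) and J the number of
    meta-analyses (6 or 10).
    """
    return dict(_EFFECT_VECTORS)


@dataclass(frozen=True)
class OEFixture:
    """One worked-example cell: observed/expected significant-trial counts.

    ``n_preferred`` is the trial count that reproduces the printed binomial
    p-value; ``n_header`` and ``n_text`` record the two counts stated in the
    source (before/after merging or splitting of trials).  ``suspect`` marks
    cells with internally inconsistent printed values (e.g. E > N); no
    worked-example check should rely on those.
    """

    network: str           # "antidepressant" | "antipsychotic"
    source: str            # "published" | "fda"
    method: str            # "fixed" | "random" | "largest"
    O: int
    E: float
    p_printed: float
    n_preferred: int
    n_header: int
    n_text: int
    suspect: bool = False


def worked_example_counts() -> list[OEFixture]:
    """The twelve worked-example (O, E, N) cells of the two case-study networks."""
    ad_pub = dict(network="antidepressant", source="published",
                  n_preferred=50, n_header=51, n_text=50)
    ad_fda = dict(network="antidepressant", source="fda",
                  n_preferred=74, n_header=74, n_text=73)
    ap_pub = dict(network="antipsychotic", source="published",
                  n_preferred=21, n_header=20, n_text=21)
    ap_fda = dict(network="antipsychotic", source="fda",
                  n_preferred=24, n_header=24, n_text=25)
    return [
        OEFixture(method="fixed",   O=41, E=35.3, p_printed=0.05,  **ad_pub),
        OEFixture(method="random",  O=41, E=35.6, p_printed=0.06,  **ad_pub),
        OEFixture(method="largest", O=41, E=31.3, p_printed=0.002, **ad_pub),
        OEFixture(method="fixed",   O=38, E=34.5, p_printed=0.24,  **ad_fda),
        OEFixture(method="random",  O=38, E=34.6, p_printed=0.25,  **ad_fda),
        OEFixture(method="largest", O=38, E=29.0, p_printed=0.02,  **ad_fda),
        OEFixture(method="fixed",   O=19, E=18.1, p_printed=0.43,  **ap_pub),
        OEFixture(method="random",  O=19, E=18.4, p_printed=0.50,  **ap_pub),
        OEFixture(method="largest", O=19, E=16.1, p_printed=0.10,  **ap_pub),
        # The FDA antipsychotic column is internally inconsistent as printed
        # (random-effects E=34.6 exceeds N; fixed/largest p-values do not
        # round-trip under either N); retained for completeness only.
        OEFixture(method="fixed",   O=20, E=19.6, p_printed=0.53, suspect=True, **ap_fda),
        OEFixture(method="random",  O=20, E=34.6, p_printed=0.56, suspect=True, **ap_fda),
        OEFixture(method="largest", O=20, E=18.6, p_printed=0.36, suspect=True, **ap_fda),
    ]
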
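"""Run-level bookkeeping and the summary report.

Every headline percentage is recomputed from the report's own integer
fields as 100 * numerator / denominator, rounded half-up to one decimal —
the reporting convention used for platform statistics such as the fraction
of beads without viral sequence or the per-method vSAG recovery rate.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal

from .community import ParameterError


def pct(numerator: int, denominator: int, decimals: int = 1) -> float:
    """Percentage rounded half-up to ``decimals`` places."""
    if denominator <= 0:
        raise ParameterError("percentage denominator must be > 0")
    q = Decimal(1).scaleb(-decimals)
    return float(
        (Decimal(100) * Decimal(numerator) / Decimal(denominator)).quantize(
            q, rounding=ROUND_HALF_UP
        )
    )


@dataclass
class MethodCounts:
    method_label: str
    n_beads_sorted: int = 0
    n_beads_with_vsag: int = 0
    n_beads_no_viral: int = 0
    n_beads_small_data: int = 0
    gb_sequenced: float = 0.0
    n_vsags: int = 0


@dataclass
class SummaryReport:
    methods: list[MethodCounts] = field(default_factory=list)
    n_vsags: int = 0
    n_single_contig_vsags: int = 0
    n_multi_bin_beads: int = 0
    n_beads_with_contigs: int = 0
    quality_tiers: dict[str, int] = field(default_factory=dict)
    n_votus: int = 0
    n_multi_member_votus: int = 0
    n_pcs: int = 0
    n_multi_vc_pcs: int = 0
    n_vcs: int = 0
    n_amgs: int = 0
    n_amg_types: int = 0
    max_amgs_per_genome: int = 0

    # --- derived percentages (always recomputed from the integers) ---------

    def no_viral_pct(self) -> float:
        total = sum(m.n_beads_sorted for m in self.methods)
        no_viral = sum(m.n_beads_no_viral for m in self.methods)
        return pct(no_viral, total)

    def recovery_pct(self, method_label: str) -> float:
        m = self._method(method_label)
        return pct(m.n_beads_with_vsag, m.n_beads_sorted)

    def single_contig_pct(self) -> float:
        return pct(self.n_single_contig_vsags, self.n_vsags)

    def multi_bin_pct(self) -> float:
        return pct(self.n_multi_bin_beads, self.n_beads_with_contigs)

    def multi_vc_pc_pct(self) -> float:
        return pct(self.n_multi_vc_pcs, self.n_pcs)

    def multi_member_votu_pct(self) -> float:
        return pct(self.n_multi_member_votus, self.n_votus)

    def vsags_per_gb(self, method_label: str) -> float:
        m = self._method(method_label)
        if m.gb_sequenced <= 0:
            raise ParameterError("gb_sequenced must be > 0")
        return round(m.n_vsags / m.gb_sequenced, 1)

    def _method(self, label: str) -> MethodCounts:
        for m in self.methods:
            if m.method_label == label:
                return m
        raise KeyError(label)

    def as_text(self) -> str:
        lines = ["# run summary"]
        for m in self.methods:
            lines.append(
                f"method {m.method_label}: sorted={m.n_beads_sorted} "
                f"with_vsag={m.n_beads_with_vsag} "
                f"(recovery {self.recovery_pct(m.method_label)}%) "
                f"no_viral={m.n_beads_no_viral} small_data={m.n_beads_small_data}"
            )
        if self.methods and sum(m.n_beads_sorted for m in self.methods):
            lines.append(f"no-viral beads: {self.no_viral_pct()}%")
        if self.n_vsags:
            lines.append(
                f"vSAGs: {self.n_vsags} "
                f"(single-contig {self.single_contig_pct()}%)"
            )
        if self.n_beads_with_contigs:
            lines.append(f"multi-bin beads: {self.multi_bin_pct()}%")
        if self.quality_tiers:
            lines.append(
                "quality tiers: "
                + ", ".join(f"{k}={v}" for k, v in sorted(self.quality_tiers.items()))
            )
        if self.n_votus:
            lines.append(
                f"vOTUs: {self.n_votus} "
                f"(multi-member {self.multi_member_votu_pct()}%)"
            )
        if self.n_pcs:
            lines.append(
                f"PCs: {self.n_pcs} (in multiple VCs {self.multi_vc_pc_pct()}%)"
            )
        if self.n_vcs:
            lines.append(f"VCs: {self.n_vcs}")
        if self.n_amgs:
            lines.append(
                f"AMGs: {self.n_amgs} of {self.n_amg_types} types "
                f"(max per genome {self.max_amgs_per_genome})"
            )
        return "\n".join(lines) + "\n"


def summarize_run(
    methods: list[MethodCounts],
    n_vsags: int = 0,
    n_single_contig_vsags: int = 0,
    n_multi_bin_beads: int = 0,
    n_beads_with_contigs: int = 0,
    quality_tiers: dict[str, int] | None = None,
    n_votus: int = 0,
    n_multi_member_votus: int = 0,
    n_pcs: int = 0,
    n_multi_vc_pcs: int = 0,
    n_vcs: int = 0,
    n_amgs: int = 0,
    n_amg_types: int = 0,
    max_amgs_per_genome: int = 0,
) -> SummaryReport:
    """Assemble the run summary from integer bookkeeping fields."""
    if not methods or all(m.n_beads_sorted == 0 for m in methods):
        raise ParameterError("summary requires at least one method with sorted beads")
    return SummaryReport(
        methods=methods,
        n_vsags=n_vsags,
        n_single_contig_vsags=n_single_contig_vsags,
        n_multi_bin_beads=n_multi_bin_beads,
        n_beads_with_contigs=n_beads_with_contigs,
        quality_tiers=dict(quality_tiers or {}),
        n_votus=n_votus,
        n_multi_member_votus=n_multi_member_votus,
        n_pcs=n_pcs,
        n_multi_vc_pcs=n_multi_vc_pcs,
        n_vcs=n_vcs,
        n_amgs=n_amgs,
        n_amg_types=n_amg_types,
        max_amgs_per_genome=max_amgs_per_genome,
    )
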
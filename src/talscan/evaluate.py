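"""Score pipeline output against a synthetic cohort's planted ground truth."""

from __future__ import annotations

from dataclasses import dataclass, field

from talscan.pipeline import GenomeResult
from talscan.simulate import GroundTruth


@dataclass
class RecoveryReport:
    """Per-aspect agreement between pipeline output and planted truth.

    Each entry counts (matches, total); rates are fractions in [0, 1].
    """

    aspects: dict[str, tuple[int, int]] = field(default_factory=dict)

    def rate(self, aspect: str) -> float:
        ok, total = self.aspects[aspect]
        return ok / total if total else 1.0

    def rates(self) -> dict[str, float]:
        return {a: self.rate(a) for a in self.aspects}

    def _add(self, aspect: str, ok: bool) -> None:
        m, t = self.aspects.get(aspect, (0, 0))
        self.aspects[aspect] = (m + int(ok), t + 1)


def score_recovery(results: list[GenomeResult], truth: GroundTruth) -> RecoveryReport:
    """Compare recovered module order, tail-unit roles, lysin classes, DA
    groups, LT families, temperate flags, size groups and arrangement
    patterns against the generator's planted ground truth."""
    rep = RecoveryReport()
    by_id = {r.genome_id: r for r in results}
    for gid, t in truth.genomes.items():
        r = by_id[gid]
        rep._add("module_order", r.module_order() == t.module_order)
        lay = r.layout
        rep._add("tmp", (lay.tmp_id if lay else None) == t.tmp_id)
        rep._add("dit", (lay.dit_id if lay else None) == t.dit_id)
        rep._add("tal", (lay.tal_id if lay else None) == t.tal_id)
        rep._add("temperate", r.temperate.is_temperate == t.temperate)
        rep._add("size_group", r.size_group == t.size_group)
        rep._add("arrangement", r.arrangement == t.arrangement)

        calls = {c.gene_id: c for c in r.lysin_calls()}
        # every planted lysin recovered with the right class/DA/family
        for lg in t.lysins.values():
            call = calls.get(lg.gene_id)
            rep._add("lysin_class", call is not None and call.tal_class == lg.tal_class)
            rep._add("da_group", call is not None and call.da_group == lg.da_group)
            if lg.lt_family != "not_applicable":
                rep._add("lt_family", call is not None and call.lt_family == lg.lt_family)
            if lg.tal_class in ("TMP_LT", "GDPD"):
                rep._add("catalytic", call is not None and call.catalytic_ok)
        # no spurious lysin calls either
        for gid2, call in calls.items():
            rep._add("no_spurious_call", gid2 in t.lysins)
    return rep
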
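import dataclasses
import itertools

import numpy as np
import pytest

from alleleforge.design import (PRIMER_PAIRS, PRIMER_ROLES, DesignResult,
                                FailedTask, PrimerDesignError,
                                assemble_in_silico, build_edited_locus,
                                candidate_penalty, compute_design_regions,
                                design_task, make_overhangs, pick_primer,
                                predict_edited_genome)
from alleleforge.errors import AssemblyJunctionMismatch
from alleleforge.io import MutationTask, VectorSequence
from alleleforge.params import DesignParameters
from alleleforge.sequence import gc_fraction, hamming, reverse_complement
from alleleforge.thermo import (hairpin_tm, homodimer_tm,
                                melting_temperature)
from alleleforge.validate import AnchoredLocus, validate_task


def anchored_locus(task, genome, params):
    res = validate_task(task, genome, params)
    assert isinstance(res, AnchoredLocus)
    return res


class TestEditedLocus:
    def test_substitution_window_geometry(self, fx, default_params):
        task = next(t for t in fx.tasks if t.kind == "substitution")
        loc = anchored_locus(task, fx.genome, default_params)
        edited = build_edited_locus(loc, task, default_params)
        assert hamming(edited.edited_context, task.context) == 1
        assert len(edited.junction_window) == default_params.overlap_len
        assert edited.junction_window[9] == task.alt_allele
        # window flanks are untouched genome sequence
        ws = edited.window_start
        assert edited.junction_window[:9] == task.context[ws:ws + 9]

    def test_indel_lengths(self, fx, default_params):
        for kind, delta in (("insertion", 1), ("deletion", -1)):
            task = next(t for t in fx.tasks if t.kind == kind)
            loc = anchored_locus(task, fx.genome, default_params)
            edited = build_edited_locus(loc, task, default_params)
            assert len(edited.edited_context) == len(task.context) + delta

    def test_edit_near_context_end_is_clipped(self, default_params):
        ctx = "ACGT" * 10
        task = MutationTask("t", ctx, 2, ctx[2], "A")
        loc = AnchoredLocus("t", "chr", 0, 2)
        with pytest.raises(PrimerDesignError, match="no room") as exc:
            build_edited_locus(loc, task, default_params)
        assert exc.value.reason == "DESIGN_WINDOW_CLIPPED"


class TestDesignRegions:
    def _edited(self, fx, params):
        task = next(t for t in fx.tasks if t.kind == "substitution")
        loc = anchored_locus(task, fx.genome, params)
        return build_edited_locus(loc, task, params)

    def test_degenerate_range_is_single_position(self, fx):
        params = DesignParameters(uha_min=600, uha_max=600)
        edited = self._edited(fx, params)
        regions = compute_design_regions(edited, _toy_vector(), params)
        assert len(regions.odr_uha) == 1
        assert regions.odr_uha[0] == edited.window_end - 600

    def test_range_width_arithmetic(self, fx, default_params):
        edited = self._edited(fx, default_params)
        regions = compute_design_regions(edited, _toy_vector(),
                                         default_params)
        assert len(regions.odr_uha) == 301     # 800 - 500 + 1
        assert len(regions.odr_dha) == 301

    def test_dis1_truncated_to_vector_end(self, fx):
        params = DesignParameters(dis1_min=50, dis1_max=10_000)
        edited = self._edited(fx, params)
        vec = _toy_vector()
        regions = compute_design_regions(edited, vec, params)
        assert regions.odr_dis1[-1] == len(vec)


def _toy_vector():
    rng = np.random.default_rng(3)
    mid = "".join(rng.choice(list("ACGT"), 260))
    return VectorSequence("A" * 20 + mid + "C" * 20)


class TestOverhangs:
    def test_tails_follow_convention(self, fx, default_params):
        task = next(t for t in fx.tasks if t.kind == "substitution")
        loc = anchored_locus(task, fx.genome, default_params)
        edited = build_edited_locus(loc, task, default_params)
        vec = _toy_vector()

        five_p = default_params.override(vector_end_convention="5prime")
        tails = make_overhangs(edited, vec, five_p)
        assert tails["primer-1"] == "A" * 20
        assert tails["primer-4"] == "G" * 20

        circ = make_overhangs(edited, vec, default_params)
        assert circ["primer-1"] == "C" * 20
        assert circ["primer-4"] == "T" * 20

        for t in (tails, circ):
            assert all(len(v) == 20 for v in t.values())
            assert t["primer-2"] == reverse_complement(t["primer-3"])
            assert t["primer-3"] == edited.junction_window


def brute_force_pick(template, odr, orientation, params):
    """Independent exhaustive argmin over all (anchor, length) candidates,
    scored with string-based thermodynamics (no prefix sums)."""
    best, best_key = None, None
    for anchor in odr:
        for length in range(params.match_len_min, params.match_len_max + 1):
            s, e = ((anchor, anchor + length) if orientation == "fwd"
                    else (anchor - length, anchor))
            if s < 0 or e > len(template):
                continue
            site = template[s:e]
            if "N" in site:
                continue
            tm = melting_temperature(site, params.salt_mM, params.oligo_nM,
                                     params.divalent_mM)
            gc = gc_fraction(site)
            if not (params.tm_min <= tm <= params.tm_max
                    and params.gc_min <= gc <= params.gc_max):
                continue
            match = site if orientation == "fwd" else reverse_complement(site)
            pen = candidate_penalty(
                tm, gc,
                homodimer_tm(match, params.salt_mM, params.oligo_nM,
                             params.divalent_mM),
                hairpin_tm(match, params.salt_mM, params.oligo_nM,
                           params.divalent_mM),
                params)
            key = (round(pen, 9), length, s)
            if best_key is None or key < best_key:
                best, best_key = (match, s, e, pen), key
    return best


class TestPickPrimer:
    def test_single_admissible_window_returned(self):
        params = DesignParameters(tm_min=0, tm_opt=60, tm_max=200,
                                  gc_min=0, gc_opt=0.5, gc_max=1,
                                  match_len_min=18, match_len_max=18)
        template = "".join(np.random.default_rng(1).choice(list("ACGT"), 60))
        primer = pick_primer(template, [10], "fwd", params)
        assert primer.match == template[10:28]

    def test_matches_bruteforce_argmin_on_random_templates(self):
        rng = np.random.default_rng(17)
        params = DesignParameters()
        for trial in range(12):
            template = "".join(rng.choice(list("ACGT"), 320))
            orientation = "fwd" if trial % 2 == 0 else "rev"
            odr = range(40, 90) if orientation == "fwd" else range(230, 280)
            expected = brute_force_pick(template, odr, orientation, params)
            if expected is None:
                with pytest.raises(PrimerDesignError):
                    pick_primer(template, odr, orientation, params)
                continue
            got = pick_primer(template, odr, orientation, params)
            assert (got.match, got.site_start, got.site_end) == expected[:3]
            assert got.penalty == pytest.approx(expected[3], abs=1e-9)

    def test_impossible_tm_reports_dominant_reason(self):
        params = DesignParameters(tm_min=90, tm_opt=92, tm_max=95)
        template = "".join(np.random.default_rng(2).choice(list("ACGT"), 100))
        with pytest.raises(PrimerDesignError) as exc:
            pick_primer(template, range(10, 40), "fwd", params)
        assert "low tm" in str(exc.value) and "ok 0" in str(exc.value)


class TestDesignTask:
    def test_successful_design_structure(self, one_result, default_params):
        r = one_result
        assert set(r.primers) == set(PRIMER_ROLES)
        for a, b in PRIMER_PAIRS:
            assert a in r.primers and b in r.primers
        for role, p in r.primers.items():
            assert 18 <= len(p.match) <= 25
            expected_tail = 0 if role.startswith("test") else 20
            assert len(p.tail) == expected_tail
        assert default_params.uha_min <= len(r.uha_seq) <= default_params.uha_max
        assert default_params.dha_min <= len(r.dha_seq) <= default_params.dha_max
        assert r.uha_amplicon_len == len(r.uha_seq) + 20
        assert r.dha_amplicon_len == len(r.dha_seq) + 20

    def test_verification_primer_spacing(self, designed, default_params):
        for r in designed[0]:
            uis = r.uha_start - r.tp1_start
            assert default_params.uis_min <= uis <= default_params.uis_max
            dis2 = r.tp3_edge - r.dha_end
            assert default_params.dis2_min <= dis2 <= default_params.dis2_max
            assert default_params.dis1_min <= r.tp2_edge <= default_params.dis1_max

    def test_determinism(self, fx, by_kind):
        task, _ = by_kind["substitution"]
        r1 = design_task(task, fx.genome, fx.vector)
        r2 = design_task(task, fx.genome, fx.vector)
        assert isinstance(r1, DesignResult) and r1 == r2

    def test_impossible_constraints_route_to_failed_task(self, fx):
        params = DesignParameters(tm_min=90, tm_opt=92, tm_max=95)
        out = design_task(fx.tasks[0], fx.genome, fx.vector, params)
        assert isinstance(out, FailedTask)
        assert out.stage == "primer_design"
        assert out.reason == "NO_ADMISSIBLE_PRIMER"

    def test_validation_failure_routes_to_failed_task(self, fx):
        bad = dataclasses.replace(fx.tasks[0], id="bad",
                                  context=fx.tasks[0].context[:1000],
                                  index=500,
                                  ref_allele=fx.tasks[0].context[500])
        out = design_task(bad, fx.genome, fx.vector)
        assert isinstance(out, FailedTask) and out.stage == "validation"


class TestAssembly:
    def test_circle_length_and_window_count(self, one_result, fx):
        circle = assemble_in_silico(one_result, fx.vector)
        insert = one_result.dha_end - one_result.uha_start
        assert len(circle) == len(fx.vector) + insert
        assert circle.count(one_result.edited.junction_window) == 1
        assert circle.startswith(fx.vector.bases[:50])

    def test_corrupted_tail_raises_junction_mismatch(self, one_result, fx):
        p1 = one_result.primers["primer-1"]
        bad_tail = ("A" if p1.tail[0] != "A" else "C") + p1.tail[1:]
        bad = dataclasses.replace(
            one_result,
            primers={**one_result.primers,
                     "primer-1": dataclasses.replace(p1, tail=bad_tail)})
        with pytest.raises(AssemblyJunctionMismatch):
            assemble_in_silico(bad, fx.vector)

    def test_five_prime_convention_cannot_circularize(self, fx):
        params = DesignParameters(vector_end_convention="5prime")
        for task in fx.tasks:
            out = design_task(task, fx.genome, fx.vector, params)
            if isinstance(out, DesignResult):
                with pytest.raises(AssemblyJunctionMismatch,
                                   match="cannot circularize"):
                    assemble_in_silico(out, fx.vector)
                return
        pytest.skip("no successful design under the 5prime convention")


class TestCrossovers:
    def test_substitution_round_trip(self, fx, by_kind):
        task, r = by_kind["substitution"]
        plasmid = assemble_in_silico(r, fx.vector)
        pred = predict_edited_genome(r, fx.genome, plasmid)
        contig = r.edited.anchored.contig
        before = fx.genome.contigs[contig]
        after = pred.edited_genome.contigs[contig]
        assert len(after) == len(before)
        assert hamming(after, before) == 1
        pos = r.edited.anchored.mut_genome_pos
        assert after[pos] == task.alt_allele and before[pos] == task.ref_allele
        assert pred.revertant.contigs[contig] == before

    def test_verification1_product_on_integrant_not_wild_type(self, fx,
                                                               by_kind):
        task, r = by_kind["substitution"]
        plasmid = assemble_in_silico(r, fx.vector)
        pred = predict_edited_genome(r, fx.genome, plasmid)
        contig = r.edited.anchored.contig
        tp1, tp2 = r.primers["test-primer-1"], r.primers["test-primer-2"]
        tp2_site = reverse_complement(tp2.match)
        integrant = pred.integrant.contigs[contig]
        wild = fx.genome.contigs[contig]
        # the reverse verification primer binds the backbone: no site on
        # wild type (false-positive check), exactly one on the integrant
        assert tp2_site not in wild and tp2.match not in wild
        i1 = integrant.find(tp1.match)
        i2 = integrant.find(tp2_site)
        assert i1 >= 0 and i2 > i1
        assert (i2 + len(tp2_site)) - i1 == pred.verification1_len

    @pytest.mark.parametrize("kind,delta", [("insertion", 1),
                                            ("deletion", -1)])
    def test_indel_amplicons_shift_by_one(self, fx, by_kind, kind, delta):
        if kind not in by_kind:
            pytest.skip(f"no designable {kind} task in this fixture")
        task, r = by_kind[kind]
        plasmid = assemble_in_silico(r, fx.vector)
        pred = predict_edited_genome(r, fx.genome, plasmid)
        contig = r.edited.anchored.contig
        before = fx.genome.contigs[contig]
        after = pred.edited_genome.contigs[contig]
        assert len(after) - len(before) == delta
        # verification-2 product measured on the edited genome
        tp1, tp3 = r.primers["test-primer-1"], r.primers["test-primer-3"]
        i1 = after.find(tp1.match)
        i3 = after.find(reverse_complement(tp3.match))
        assert (i3 + len(tp3.match)) - i1 == pred.verification2_len
        # against the unedited genome the same primers would span one
        # base more/less
        w1 = before.find(tp1.match)
        w3 = before.find(reverse_complement(tp3.match))
        assert ((i3 + len(tp3.match)) - i1) - ((w3 + len(tp3.match)) - w1) \
            == delta
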
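import itertools

import pytest

from famvar.cascade import (
    consensus_callers,
    filter_functional_class,
    filter_rare,
    predict_deleterious,
    remove_paternal,
    remove_shared_with_unaffected,
    run_cascade,
    CascadeAudit,
)
from famvar.core.types import (
    CohortCallset,
    FilterConfig,
    FunctionalClass,
    VariantAnnotation,
    VariantKey,
)
from famvar.errors import ConfigError, MissingAnnotationError, PedigreeError

V1 = VariantKey.of("chr1", 100, "A", "T")
V2 = VariantKey.of("chr2", 200, "C", "G")


def ann(key, cls=FunctionalClass.nonsynonymous_SNV, sift=None, polyphen=None, maf=None):
    return VariantAnnotation(
        key=key,
        gene="G",
        functional_class=cls,
        sift=sift,
        polyphen_hvar=polyphen,
        maf=maf or {},
    )


class TestConsensusCallers:
    def test_intersection_requires_both(self):
        callset = CohortCallset(
            ["a"],
            per_caller={"x": {V1: frozenset("a")}, "y": {V1: frozenset("a")}},
        )
        merged = consensus_callers(callset, "intersection")
        assert merged.present(V1, "a")

    def test_single_caller_discordance_removed(self):
        callset = CohortCallset(
            ["a"],
            per_caller={"x": {V1: frozenset("a")}, "y": {}},
        )
        merged = consensus_callers(callset, "intersection")
        assert merged.variants() == ()

    def test_union_keeps_either(self):
        callset = CohortCallset(
            ["a"],
            per_caller={"x": {V1: frozenset("a")}, "y": {}},
        )
        assert consensus_callers(callset, "union").present(V1, "a")

    def test_single_caller_identity_either_mode(self):
        callset = CohortCallset(["a"], per_caller={"x": {V1: frozenset("a")}})
        for mode in ("intersection", "union"):
            merged = consensus_callers(callset, mode)
            assert merged.merged == {V1: frozenset("a")}

    def test_output_is_merged_only(self):
        callset = CohortCallset(["a"], per_caller={"x": {V1: frozenset("a")}})
        merged = consensus_callers(callset)
        assert merged.is_merged and not merged.per_caller

    def test_unknown_mode_rejected(self):
        callset = CohortCallset(["a"], per_caller={"x": {}})
        with pytest.raises(ConfigError):
            consensus_callers(callset, "majority")


class TestRemoveSharedWithUnaffected:
    def test_control_shared_removed(self, study_pedigree, make_merged_callset):
        callset = make_merged_callset(["1", "3"], {("chr1", 100, "A", "T"): {"1", "3"}})
        out = remove_shared_with_unaffected(callset, study_pedigree, ["3"])
        assert out.variants() == ()

    def test_affected_only_retained(self, study_pedigree, make_merged_callset):
        callset = make_merged_callset(["2", "3"], {("chr1", 100, "A", "T"): {"2"}})
        out = remove_shared_with_unaffected(callset, study_pedigree, ["3"])
        assert out.variants() == (V1,)

    def test_study_shared_sister_variant_retained(self, study_pedigree, make_merged_callset):
        # present in three affected sisters, absent in the unaffected sister
        callset = make_merged_callset(
            ["1", "2", "3", "4"], {("chr16", 30767746, "C", "T"): {"1", "2", "4"}}
        )
        out = remove_shared_with_unaffected(callset, study_pedigree, ["3"])
        assert len(out.variants()) == 1

    def test_no_affected_carrier_dropped(self, study_pedigree, make_merged_callset):
        callset = make_merged_callset(["8", "3"], {("chr1", 100, "A", "T"): {"8"}})
        out = remove_shared_with_unaffected(callset, study_pedigree, ["3"])
        assert out.variants() == ()

    def test_affected_control_rejected(self, study_pedigree, make_merged_callset):
        callset = make_merged_callset(["1"], {})
        with pytest.raises(ConfigError):
            remove_shared_with_unaffected(callset, study_pedigree, ["1"])


class TestAnnotationFilters:
    def test_kept_classes(self):
        anns = {
            V1: ann(V1, FunctionalClass.nonsynonymous_SNV),
            V2: ann(V2, FunctionalClass.synonymous),
        }
        kept = filter_functional_class(anns, FilterConfig().kept_classes)
        assert set(kept) == {V1}

    def test_stopgain_kept(self):
        anns = {V1: ann(V1, FunctionalClass.stopgain)}
        assert set(filter_functional_class(anns, FilterConfig().kept_classes)) == {V1}

    def test_rare_catalogued_kept(self):
        anns = {V1: ann(V1, maf={"ESP6500": 0.0005})}
        assert set(filter_rare(anns, 0.001)) == {V1}

    def test_common_removed(self):
        anns = {V1: ann(V1, maf={"ESP6500": 0.005})}
        assert filter_rare(anns, 0.001) == {}

    def test_novel_kept(self):
        anns = {V1: ann(V1)}
        assert set(filter_rare(anns, 0.001)) == {V1}


class TestPredictDeleterious:
    config = FilterConfig()

    def test_polyphen_rescues_tolerated_sift(self):
        assert predict_deleterious(ann(V1, sift=0.34, polyphen=0.98), self.config)

    def test_sift_rescues_benign_polyphen(self):
        assert predict_deleterious(ann(V1, sift=0.02, polyphen=0.00), self.config)

    def test_both_tolerated_false(self):
        assert not predict_deleterious(ann(V1, sift=0.50, polyphen=0.20), self.config)

    def test_stopgain_unconditional(self):
        assert predict_deleterious(ann(V1, FunctionalClass.stopgain), self.config)

    def test_splicing_unconditional(self):
        assert predict_deleterious(ann(V1, FunctionalClass.splicing), self.config)

    def test_sift_band_boundary_is_tolerant(self):
        # damaging means strictly below 0.05
        assert not predict_deleterious(ann(V1, sift=0.05, polyphen=0.1), self.config)

    def test_polyphen_band_boundary_is_damaging(self):
        # possibly damaging starts at 0.447 inclusive
        assert predict_deleterious(ann(V1, sift=0.5, polyphen=0.447), self.config)

    def test_scoreless_nonsynonymous_false_with_warning(self):
        audit = CascadeAudit()
        assert not predict_deleterious(ann(V1), self.config, audit)
        assert audit.warnings


class TestRemovePaternal:
    def test_mother_transmitted_variant_retained(self, study_pedigree, make_merged_callset):
        # absent in the father, present in mother and both daughters
        callset = make_merged_callset(
            ["9", "2", "5", "6"], {("chr5", 58147140, "G", "A"): {"2", "5", "6"}}
        )
        out = remove_paternal(callset, study_pedigree, "9", ["5", "6"])
        assert out.carriers(VariantKey.of("chr5", 58147140, "G", "A")) == {"2", "5", "6"}

    def test_father_daughter_only_removed_entirely(self, study_pedigree, make_merged_callset):
        callset = make_merged_callset(["9", "5"], {("chr1", 100, "A", "T"): {"9", "5"}})
        out = remove_paternal(callset, study_pedigree, "9", ["5"])
        assert out.variants() == ()

    def test_father_and_non_daughter_unchanged(self, trio_pedigree, make_merged_callset):
        # variant in father F and unrelated sister S: S is untouched
        callset = make_merged_callset(["F", "D", "S"], {("chr1", 100, "A", "T"): {"F", "S"}})
        out = remove_paternal(callset, trio_pedigree, "F", ["D"])
        assert out.carriers(V1) == {"F", "S"}

    def test_only_daughter_presence_cleared(self, trio_pedigree, make_merged_callset):
        callset = make_merged_callset(
            ["F", "D", "S"], {("chr1", 100, "A", "T"): {"F", "D", "S"}}
        )
        out = remove_paternal(callset, trio_pedigree, "F", ["D"])
        assert out.carriers(V1) == {"F", "S"}

    def test_non_child_rejected(self, trio_pedigree, make_merged_callset):
        callset = make_merged_callset(["F", "S"], {})
        with pytest.raises(PedigreeError):
            remove_paternal(callset, trio_pedigree, "F", ["S"])


class TestRunCascade:
    def test_study_fixture_final_set(self, cascade_result):
        assert len(cascade_result.final_keys) == 23

    def test_every_stage_audited(self, cascade_result):
        stages = [s.stage for s in cascade_result.audit.stages]
        assert stages == [
            "caller_consensus",
            "unaffected_subtraction",
            "maf_filter",
            "functional_class_filter",
            "deleteriousness_filter",
            "paternal_removal",
            "confirmation_filter",
        ]

    def test_audit_counts_monotone(self, cascade_result):
        counts = [s.variants_in for s in cascade_result.audit.stages]
        counts.append(cascade_result.audit.stages[-1].variants_out)
        assert counts == sorted(counts, reverse=True)
        for stage in cascade_result.audit.stages:
            assert stage.variants_out <= stage.variants_in
            assert len(stage.removed_keys) == stage.variants_in - stage.variants_out

    def test_removed_keys_disjoint_from_output(self, cascade_result):
        final = set(cascade_result.final_keys)
        for stage in cascade_result.audit.stages:
            assert not (set(stage.removed_keys) & final)

    def test_control_exclusion_invariant(self, cascade_result, study_config):
        for key in cascade_result.final_keys:
            assert not (
                cascade_result.callset.carriers(key) & set(study_config.control_ids)
            )

    def test_empty_callset(self, study_pedigree, study_annotations, study_config):
        empty = CohortCallset(study_pedigree.ids, per_caller={"varscan": {}, "gatk": {}})
        result = run_cascade(empty, study_annotations, study_pedigree, study_config)
        assert result.final_keys == ()
        assert all(s.variants_in == 0 for s in result.audit.stages)

    def test_idempotent_on_own_output(
        self, cascade_result, study_annotations, study_pedigree, study_config
    ):
        again = run_cascade(
            cascade_result.callset, study_annotations, study_pedigree, study_config
        )
        assert again.callset.merged == cascade_result.callset.merged

    def test_unannotated_variant_strict_vs_lenient(
        self, study_pedigree, study_annotations, study_config, make_merged_callset
    ):
        callset = CohortCallset(
            study_pedigree.ids,
            per_caller={
                "x": {VariantKey.of("chr9", 999, "A", "G"): frozenset({"1"})}
            },
        )
        with pytest.raises(MissingAnnotationError):
            run_cascade(callset, study_annotations, study_pedigree, study_config)
        result = run_cascade(
            callset, study_annotations, study_pedigree, study_config, strict=False
        )
        assert result.final_keys == ()
        assert result.audit.warnings

    def test_stage_order_insensitive_on_fixture(
        self, study_cohort, study_annotations, study_pedigree, study_config
    ):
        """Permuting the restriction stages leaves the final set unchanged."""
        merged = consensus_callers(study_cohort, study_config.caller_mode)

        def subtraction(callset):
            return remove_shared_with_unaffected(
                callset, study_pedigree, study_config.control_ids
            )

        def rare(callset):
            live = {k: study_annotations[k] for k in callset.variants()}
            return callset.restrict(filter_rare(live, study_config.maf_threshold))

        def classes(callset):
            live = {k: study_annotations[k] for k in callset.variants()}
            return callset.restrict(
                filter_functional_class(live, study_config.kept_classes)
            )

        def deleterious(callset):
            return callset.restrict(
                [
                    k
                    for k in callset.variants()
                    if predict_deleterious(study_annotations[k], study_config)
                ]
            )

        def paternal(callset):
            out = remove_paternal(callset, study_pedigree, "9", ["5", "6"])
            return remove_paternal(out, study_pedigree, "10", ["7"])

        def confirmation(callset):
            return callset.restrict(
                [
                    k
                    for k in callset.variants()
                    if study_annotations[k].sanger_confirmed is True
                ]
            )

        reference = None
        for order in itertools.permutations(
            [subtraction, rare, classes, deleterious, paternal]
        ):
            callset = merged
            for stage in order:
                callset = stage(callset)
            final = set(confirmation(callset).variants())
            if reference is None:
                reference = final
            assert final == reference
        assert reference is not None and len(reference) == 23
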
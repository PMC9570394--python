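"""Opposite-sex verification, heterogamety calls, trans-species sharing."""

import math

import pytest

from sexlinkscan.io_formats import Sex, revcomp
from sexlinkscan.screen import CandidateMarker, SupportCounts, screen_all
from sexlinkscan.synthdata import SimulationConfig, simulate_catalog, \
    simulate_reads
from sexlinkscan.validate import (
    call_system,
    find_trans_species_markers,
    validate_markers,
    verify_sex_limited_marker,
    verify_snp_marker,
)

# 64 bp: long enough that an exact full-length match clears E <= 1e-20
CONS = "ACGTACGTACGTACGTACGTACGTACGTACGT" * 2
COL = 4  # consensus base A
Y_HAP = CONS[:COL] + "T" + CONS[COL + 1:]


def snp_marker(**kw):
    defaults = dict(
        locus_id="L1", site=COL, strategy="allele_frequency",
        system_consistency="XY_type", support=SupportCounts(),
        sex_specific_allele="T", consensus=CONS,
    )
    defaults.update(kw)
    return CandidateMarker(**defaults)


def tag_marker(**kw):
    defaults = dict(
        locus_id="L2", site=None, strategy="sex_limited",
        system_consistency="XY_type", support=SupportCounts(), consensus=CONS,
    )
    defaults.update(kw)
    return CandidateMarker(**defaults)


class TestVerifySnp:
    def test_y_copy_in_female_pool_rejects(self):
        males = [("m1", Y_HAP), ("m2", CONS)]
        females = [("f1", Y_HAP), ("f2", CONS)]
        res = verify_snp_marker(snp_marker(), males, females)
        assert res.status == "rejected_female_evidence"
        assert res.n_homogametic_occurrences == 1

    def test_male_only_y_allele_confirms(self):
        males = [(f"m{i}", Y_HAP) for i in range(5)] + [("mx", CONS)]
        females = [("f1", CONS), ("f2", CONS)]
        res = verify_snp_marker(snp_marker(), males, females)
        assert res.status == "confirmed"
        assert res.n_heterogametic_occurrences == 5

    def test_no_hits_anywhere_is_insufficient(self):
        other = "G" * len(CONS)
        res = verify_snp_marker(snp_marker(), [("m1", other)], [("f1", other)])
        assert res.status == "insufficient_data"

    def test_y_absent_from_males_is_inconsistent(self):
        res = verify_snp_marker(
            snp_marker(), [("m1", CONS)], [("f1", CONS)]
        )
        assert res.status == "rejected_male_inconsistent"

    def test_zw_marker_pools_swap_roles(self):
        marker = snp_marker(system_consistency="ZW_type")
        males = [("m1", CONS)]
        females = [("f1", Y_HAP)]
        res = verify_snp_marker(marker, males, females)
        assert res.status == "confirmed"

    def test_marker_without_allele_uses_heterozygosity_route(self):
        marker = snp_marker(strategy="heterozygosity", sex_specific_allele=None)
        males = [("m1", Y_HAP)]
        females = [("f1", CONS)]
        res = verify_snp_marker(marker, males, females)
        assert res.status == "confirmed"
        assert "heterozygosity-only" in res.note

    def test_removing_female_reads_never_unconfirms(self):
        males = [("m1", Y_HAP), ("m2", CONS)]
        females = [("f1", CONS), ("f2", CONS)]
        assert verify_snp_marker(snp_marker(), males, females).status \
            == "confirmed"
        assert verify_snp_marker(snp_marker(), males, []).status == "confirmed"


class TestVerifySexLimited:
    def test_consensus_in_female_read_rejects(self):
        males = [("m1", "AA" + CONS + "GG")]
        females = [("f1", CONS)]
        res = verify_sex_limited_marker(tag_marker(), males, females)
        assert res.status == "rejected_female_evidence"

    def test_male_only_confirms(self):
        res = verify_sex_limited_marker(
            tag_marker(), [("m1", CONS)], [("f1", "G" * 40)]
        )
        assert res.status == "confirmed"

    def test_reverse_complement_in_female_pool_rejects(self):
        tag = tag_marker(consensus="AAAACCCCGGGTTTAACCTTGGAACCTTGGAA")
        females = [("f1", revcomp(tag.consensus))]
        males = [("m1", tag.consensus)]
        strict = verify_sex_limited_marker(tag, males, females)
        assert strict.status == "rejected_female_evidence"
        # the literal text-match mode does not see the minus strand
        literal = verify_sex_limited_marker(
            tag, males, females, strand_aware=False
        )
        assert literal.status == "confirmed"

    def test_empty_pools_insufficient(self):
        assert verify_sex_limited_marker(tag_marker(), [], []).status \
            == "insufficient_data"


def binom_two_sided(k, n):
    """Independent exact two-sided binomial tail sum at p=1/2."""
    pmf = [math.comb(n, i) * 0.5 ** n for i in range(n + 1)]
    return sum(p for p in pmf if p <= pmf[k] + 1e-12)


class TestCallSystem:
    def test_clear_xy_majority(self):
        call = call_system((40, 2))
        assert call.call == "XY"
        assert call.p_value == pytest.approx(binom_two_sided(40, 42), rel=1e-9)
        assert call.p_value < 0.05

    def test_balanced_counts_undetermined(self):
        assert call_system((5, 5)).call == "undetermined"

    def test_no_markers_undetermined_without_p(self):
        call = call_system((0, 0))
        assert call.call == "undetermined"
        assert call.p_value is None

    def test_minority_markers_reported_not_dropped(self):
        markers = [snp_marker(species_id="sp")] * 9 + [
            snp_marker(system_consistency="ZW_type", species_id="sp",
                       sex_specific_allele=None)
        ]
        call = call_system(markers)
        assert call.call == "XY"
        assert len(call.excluded_markers) == 1
        assert call.excluded_markers[0].system_consistency == "ZW_type"

    def test_zw_simulation_called_zw(self):
        cfg = SimulationConfig(
            n_species=1, n_males=6, n_females=6, n_autosomal_loci=10,
            n_xy_snp_loci=15, n_y_limited_loci=5, system="ZW",
            species_tree="(sp1:1,sp2:1);", seed=8,
        )
        study = simulate_catalog(cfg)
        catalog = study.catalogs["sp1"]
        markers = screen_all(catalog, study.registry, species_id="sp1")
        pools = simulate_reads(catalog, study.registry)
        results = validate_markers(markers, pools[Sex.MALE], pools[Sex.FEMALE])
        confirmed = [r.marker for r in results if r.status == "confirmed"]
        assert call_system(confirmed).call == "ZW"


class TestTransSpecies:
    UNIFIED = {
        "sp1": {"L1": "u1", "L9": "u9"},
        "sp2": {"L7": "u1"},
        "sp3": {},
    }

    def test_planted_sharing_reported(self):
        confirmed = {
            "sp1": [snp_marker(locus_id="L1")],
            "sp2": [snp_marker(locus_id="L7")],
            "sp3": [snp_marker(locus_id="L5")],
        }
        rep = find_trans_species_markers(confirmed, self.UNIFIED)
        assert len(rep["shared"]) == 1
        assert rep["shared"][0].species == {"sp1", "sp2"}
        assert rep["maximal_sharing_set"] == {"sp1", "sp2"}

    def test_no_sharing_empty_report(self):
        confirmed = {"sp1": [snp_marker(locus_id="L9")], "sp2": []}
        rep = find_trans_species_markers(confirmed, self.UNIFIED)
        assert rep["shared"] == []
        assert rep["maximal_sharing_set"] == frozenset()

    def test_all_species_share(self):
        unified = {sp: {"L1": "u1"} for sp in ("sp1", "sp2", "sp3")}
        confirmed = {sp: [snp_marker(locus_id="L1")] for sp in unified}
        rep = find_trans_species_markers(confirmed, unified)
        assert rep["maximal_sharing_set"] == {"sp1", "sp2", "sp3"}

    def test_species_missing_from_unified_catalog(self):
        with pytest.raises(ValueError, match="sp4"):
            find_trans_species_markers(
                {"sp4": []}, self.UNIFIED
            )


class TestEndToEndValidation:
    def test_planted_loci_confirmed_and_fps_rejected(self, small_study):
        study = small_study
        sp = "sp1"
        catalog = study.catalogs[sp]
        markers = screen_all(catalog, study.registry, species_id=sp)
        pools = simulate_reads(catalog, study.registry)
        results = validate_markers(markers, pools[Sex.MALE], pools[Sex.FEMALE])
        status = {}
        for r in results:
            status.setdefault(r.marker.locus_id, set()).add(
                (r.marker.system_consistency, r.status)
            )
        planted = study.truth.sex_linked_ids(sp)
        for lid in planted:
            assert ("XY_type", "confirmed") in status[lid]
        # no planted sex-linked locus survives as a ZW-type candidate;
        # autosomal sites may pass either way by sampling chance and are
        # settled downstream by the binomial system call
        for lid in planted:
            assert ("ZW_type", "confirmed") not in status[lid]
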
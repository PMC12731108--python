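# Shipped QC threshold profiles.
#
# discovery_*  : exome discovery profile.  Genotype-level thresholds are
#                minima (pass when value >= threshold): GQ 10, alt allele
#                depth 2, depth 7, allele balance 0.1.  Site quality is
#                always a strict cut: VQSLOD > 2 (GATK VQSR cohorts) or
#                QUAL > 38 (joint-called QUAL cohorts).
# replication_ukbb : stricter whole-genome replication profile with strict
#                inequalities at the genotype level: GQ > 25, alt depth > 3,
#                depth > 10, allele balance > 0.2.
# All profiles restrict to rare variants: AF <= 1e-4 in both population
# frequency databases (missing frequency treated as 0 / unobserved).
discovery_sayo:
  min_gq: 10
  min_ad_alt: 2
  min_dp: 7
  min_ab: 0.1
  min_site_quality_vqslod: 2.0
  min_site_quality_qual: 38.0
  af_max: 1.0e-4
  strict_inequalities: false
discovery_spark:
  min_gq: 10
  min_ad_alt: 2
  min_dp: 7
  min_ab: 0.1
  min_site_quality_vqslod: 2.0
  min_site_quality_qual: 38.0
  af_max: 1.0e-4
  strict_inequalities: false
replication_ukbb:
  min_gq: 25
  min_ad_alt: 3
  min_dp: 10
  min_ab: 0.2
  min_site_quality_vqslod: 2.0
  min_site_quality_qual: 38.0
  af_max: 1.0e-4
  strict_inequalities: true
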
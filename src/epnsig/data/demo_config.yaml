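# End-to-end demo: simulate a posterior-fossa nCounter batch, normalize,
# classify PFA/PFB (+ PFA1/PFA2 and NELL2/LAMA2 strata), and run the
# clinical statistics on the packaged supratentorial patient table.
seed: 7
stages:
  simulate:
    nanostring:
      groups:
        PFA: 10
        PFB: 5
      signature_fold: 6
      out: rcc
  normalize:
    rcc_dir: rcc
    out: normalized.tsv
  classify:
    matrix: normalized.tsv
    compartment: PF
    out: assignments.tsv
  stats:
    clinical: packaged:table2
    fusion_concordance: true
    survivor_count:
      group: RELA+
      min_months: 60
    endpoint: OS
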
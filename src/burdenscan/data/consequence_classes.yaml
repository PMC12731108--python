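# Mapping from transcript-consequence terms (Sequence Ontology style, as
# emitted by VEP) to the variant classes used by the burden analysis.
#
# Loss-of-function covers predicted protein-truncating consequences:
# premature stop, start/stop loss, frameshift and canonical splice-site
# disruption.  "start_gained" terms (5'UTR uAUG creation) are deliberately
# absent: their protein-level effect is ambiguous, so they fall through to
# "other" unless a user adds them here.
#
# Terms not listed in any class are classified as "other" (and logged once
# per unknown term).  Edit freely; the file is read at import of the QC
# module and can be overridden per call.
lof:
  - stop_gained
  - stop_lost
  - start_lost
  - frameshift_variant
  - splice_acceptor_variant
  - splice_donor_variant
missense:
  - missense_variant
synonymous:
  - synonymous_variant
inframe_indel:
  - inframe_insertion
  - inframe_deletion
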
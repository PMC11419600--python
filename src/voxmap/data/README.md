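# Packaged reference data

`reference_calls.tsv` is a verbatim transcription of the published
per-neuron expression-call table for the *Ciona intestinalis/robusta*
larval CNS (VGAT, VAChT, NMDAR, AMPAR, kainate receptor; calls encoded
`+` / `0` as printed). It has 166 data rows. Known discrepancies between
the printed table and the surrounding text, reproduced here verbatim and
*not* silently resolved:

- The methods text states VAChT is expressed in "all 10 motor neurons",
  but the table lists only 6 MN rows (MN1–3, L/R).
- The text counts 11 AntRNs; the table has 10 AntRN rows.
- The text counts "fourteen" coronet cells; the table has 16 Coronet rows.
- One coronet row is printed with an internal space ("coronet 10");
  the id is kept verbatim.
- One prRN row (id 80) is all-zero, matching the text's hedge that "at
  least five of the six" prRNs are cholinergic.

`synthetic_edges.tsv` and `synthetic_transmitters.tsv` are **synthetic**
fixtures, not a transcription of the connectome wiring: they encode only
pre→post relations and transmitter identities stated in prose (pATENs
synapse onto the AMGs; PR-I photoreceptors project to prRNs and
pr-AMG RNs; PR-II photoreceptors project to pr-AMG RNs; the two VGLUT+
antenna neurons project to AntRNs and to cor-ass BVIN 60), with
representative individual ids chosen here.
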
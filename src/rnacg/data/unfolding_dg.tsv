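# Published unfolding free energies (kcal/mol, 298 K) for five RNA
# hairpins (h1-h5, 10-18 nt), the 52-nt TAR hairpin, and five duplexes
# (d1-d5, 6-10 bp): optical-melting / single-molecule experimental
# values (dg_expt), nearest-neighbor secondary-structure predictions
# (dg_mfold), and coarse-grained umbrella-sampling predictions
# (dg_model) with bootstrap errors.  n_units is nucleotides for
# hairpins, base pairs for duplexes.  sim_per_window is the production
# molecular-dynamics length per umbrella window in microseconds.
label	kind	n_units	dg_expt	dg_expt_err	dg_mfold	dg_model	dg_model_err	sim_per_window_us
h1	hairpin	10	-3.5	0.3	-5.3	-2.8	0.12	1
h2	hairpin	10	-0.3	0.1	0.9	-1.4	0.12	1
h3	hairpin	12	-4.4	0.2	-3.4	-4.8	0.14	1
h4	hairpin	14	-2.2	0.08	-2.2	-5.7	0.15	1
h5	hairpin	18	-8.2	0.2	-8.4	-7.9	0.22	1
TAR	hairpin	52	-21.5	4.3	-31.3	-29.7	0.36	0.1
d1	duplex	6	-7.56	0.3	-11.4	-7.8	0.15	1
d2	duplex	6	-4.95	0.2	-9.8	-7.5	0.14	1
d3	duplex	8	-12.32	1.2	-17.0	-12.8	0.17	1
d4	duplex	8	-10.11	0.2	-14.7	-11.1	0.18	1
d5	duplex	10	-12.69	0.5	-18.1	-14.0	0.19	1
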
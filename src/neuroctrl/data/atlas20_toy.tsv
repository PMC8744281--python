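label	hemisphere	compartment
lh.dmn_1	L	cortical
rh.dmn_2	R	cortical
lh.dmn_3	L	cortical
lh.da_1	L	cortical
rh.da_2	R	cortical
lh.fcn_1	L	cortical
rh.fcn_2	R	cortical
lh.ln_1	L	cortical
rh.ln_2	R	cortical
lh.smn_1	L	cortical
rh.smn_2	R	cortical
lh.smn_3	L	cortical
lh.vn_1	L	cortical
rh.vn_2	R	cortical
lh.va_1	L	cortical
rh.va_2	R	cortical
lh.thalamus	L	subcortical
lh.putamen	L	subcortical
rh.thalamus	R	subcortical
rh.putamen	R	subcortical
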
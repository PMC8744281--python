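label	system	count
lh.dmn_1	DMN	80
lh.dmn_1	DA	20
rh.dmn_2	DMN	80
rh.dmn_2	DA	20
lh.dmn_3	DMN	80
lh.dmn_3	DA	20
lh.da_1	DA	80
lh.da_1	FCN	20
rh.da_2	DA	80
rh.da_2	FCN	20
lh.fcn_1	FCN	80
lh.fcn_1	LN	20
rh.fcn_2	FCN	80
rh.fcn_2	LN	20
lh.ln_1	LN	80
lh.ln_1	SMN	20
rh.ln_2	LN	80
rh.ln_2	SMN	20
lh.smn_1	SMN	80
lh.smn_1	VN	20
rh.smn_2	SMN	80
rh.smn_2	VN	20
lh.smn_3	SMN	80
lh.smn_3	VN	20
lh.vn_1	VN	80
lh.vn_1	VA	20
rh.vn_2	VN	80
rh.vn_2	VA	20
lh.va_1	VA	80
lh.va_1	DMN	20
rh.va_2	VA	80
rh.va_2	DMN	20
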
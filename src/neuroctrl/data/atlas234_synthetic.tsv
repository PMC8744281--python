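label	hemisphere	compartment
lh.bankssts_1	L	cortical
lh.bankssts_2	L	cortical
lh.bankssts_3	L	cortical
lh.bankssts_4	L	cortical
lh.caudalanteriorcingulate_1	L	cortical
lh.caudalanteriorcingulate_2	L	cortical
lh.caudalanteriorcingulate_3	L	cortical
lh.caudalanteriorcingulate_4	L	cortical
lh.caudalmiddlefrontal_1	L	cortical
lh.caudalmiddlefrontal_2	L	cortical
lh.caudalmiddlefrontal_3	L	cortical
lh.caudalmiddlefrontal_4	L	cortical
lh.cuneus_1	L	cortical
lh.cuneus_2	L	cortical
lh.cuneus_3	L	cortical
lh.cuneus_4	L	cortical
lh.entorhinal_1	L	cortical
lh.entorhinal_2	L	cortical
lh.entorhinal_3	L	cortical
lh.entorhinal_4	L	cortical
lh.frontalpole_1	L	cortical
lh.frontalpole_2	L	cortical
lh.frontalpole_3	L	cortical
lh.frontalpole_4	L	cortical
lh.fusiform_1	L	cortical
lh.fusiform_2	L	cortical
lh.fusiform_3	L	cortical
lh.fusiform_4	L	cortical
lh.inferiorparietal_1	L	cortical
lh.inferiorparietal_2	L	cortical
lh.inferiorparietal_3	L	cortical
lh.inferiorparietal_4	L	cortical
lh.inferiortemporal_1	L	cortical
lh.inferiortemporal_2	L	cortical
lh.inferiortemporal_3	L	cortical
lh.insula_1	L	cortical
lh.insula_2	L	cortical
lh.insula_3	L	cortical
lh.isthmuscingulate_1	L	cortical
lh.isthmuscingulate_2	L	cortical
lh.isthmuscingulate_3	L	cortical
lh.lateraloccipital_1	L	cortical
lh.lateraloccipital_2	L	cortical
lh.lateraloccipital_3	L	cortical
lh.lateralorbitofrontal_1	L	cortical
lh.lateralorbitofrontal_2	L	cortical
lh.lateralorbitofrontal_3	L	cortical
lh.lingual_1	L	cortical
lh.lingual_2	L	cortical
lh.lingual_3	L	cortical
lh.medialorbitofrontal_1	L	cortical
lh.medialorbitofrontal_2	L	cortical
lh.medialorbitofrontal_3	L	cortical
lh.middletemporal_1	L	cortical
lh.middletemporal_2	L	cortical
lh.middletemporal_3	L	cortical
lh.paracentral_1	L	cortical
lh.paracentral_2	L	cortical
lh.paracentral_3	L	cortical
lh.parahippocampal_1	L	cortical
lh.parahippocampal_2	L	cortical
lh.parahippocampal_3	L	cortical
lh.parsopercularis_1	L	cortical
lh.parsopercularis_2	L	cortical
lh.parsopercularis_3	L	cortical
lh.parsorbitalis_1	L	cortical
lh.parsorbitalis_2	L	cortical
lh.parsorbitalis_3	L	cortical
lh.parstriangularis_1	L	cortical
lh.parstriangularis_2	L	cortical
lh.parstriangularis_3	L	cortical
lh.pericalcarine_1	L	cortical
lh.pericalcarine_2	L	cortical
lh.pericalcarine_3	L	cortical
lh.postcentral_1	L	cortical
lh.postcentral_2	L	cortical
lh.postcentral_3	L	cortical
lh.posteriorcingulate_1	L	cortical
lh.posteriorcingulate_2	L	cortical
lh.posteriorcingulate_3	L	cortical
lh.precentral_1	L	cortical
lh.precentral_2	L	cortical
lh.precentral_3	L	cortical
lh.precuneus_1	L	cortical
lh.precuneus_2	L	cortical
lh.precuneus_3	L	cortical
lh.rostralanteriorcingulate_1	L	cortical
lh.rostralanteriorcingulate_2	L	cortical
lh.rostralanteriorcingulate_3	L	cortical
lh.rostralmiddlefrontal_1	L	cortical
lh.rostralmiddlefrontal_2	L	cortical
lh.rostralmiddlefrontal_3	L	cortical
lh.superiorfrontal_1	L	cortical
lh.superiorfrontal_2	L	cortical
lh.superiorfrontal_3	L	cortical
lh.superiorparietal_1	L	cortical
lh.superiorparietal_2	L	cortical
lh.superiorparietal_3	L	cortical
lh.superiortemporal_1	L	cortical
lh.superiortemporal_2	L	cortical
lh.superiortemporal_3	L	cortical
lh.supramarginal_1	L	cortical
lh.supramarginal_2	L	cortical
lh.supramarginal_3	L	cortical
lh.temporalpole_1	L	cortical
lh.temporalpole_2	L	cortical
lh.temporalpole_3	L	cortical
lh.transversetemporal_1	L	cortical
lh.transversetemporal_2	L	cortical
lh.transversetemporal_3	L	cortical
rh.bankssts_1	R	cortical
rh.bankssts_2	R	cortical
rh.bankssts_3	R	cortical
rh.bankssts_4	R	cortical
rh.caudalanteriorcingulate_1	R	cortical
rh.caudalanteriorcingulate_2	R	cortical
rh.caudalanteriorcingulate_3	R	cortical
rh.caudalanteriorcingulate_4	R	cortical
rh.caudalmiddlefrontal_1	R	cortical
rh.caudalmiddlefrontal_2	R	cortical
rh.caudalmiddlefrontal_3	R	cortical
rh.caudalmiddlefrontal_4	R	cortical
rh.cuneus_1	R	cortical
rh.cuneus_2	R	cortical
rh.cuneus_3	R	cortical
rh.cuneus_4	R	cortical
rh.entorhinal_1	R	cortical
rh.entorhinal_2	R	cortical
rh.entorhinal_3	R	cortical
rh.entorhinal_4	R	cortical
rh.frontalpole_1	R	cortical
rh.frontalpole_2	R	cortical
rh.frontalpole_3	R	cortical
rh.frontalpole_4	R	cortical
rh.fusiform_1	R	cortical
rh.fusiform_2	R	cortical
rh.fusiform_3	R	cortical
rh.fusiform_4	R	cortical
rh.inferiorparietal_1	R	cortical
rh.inferiorparietal_2	R	cortical
rh.inferiorparietal_3	R	cortical
rh.inferiorparietal_4	R	cortical
rh.inferiortemporal_1	R	cortical
rh.inferiortemporal_2	R	cortical
rh.inferiortemporal_3	R	cortical
rh.insula_1	R	cortical
rh.insula_2	R	cortical
rh.insula_3	R	cortical
rh.isthmuscingulate_1	R	cortical
rh.isthmuscingulate_2	R	cortical
rh.isthmuscingulate_3	R	cortical
rh.lateraloccipital_1	R	cortical
rh.lateraloccipital_2	R	cortical
rh.lateraloccipital_3	R	cortical
rh.lateralorbitofrontal_1	R	cortical
rh.lateralorbitofrontal_2	R	cortical
rh.lateralorbitofrontal_3	R	cortical
rh.lingual_1	R	cortical
rh.lingual_2	R	cortical
rh.lingual_3	R	cortical
rh.medialorbitofrontal_1	R	cortical
rh.medialorbitofrontal_2	R	cortical
rh.medialorbitofrontal_3	R	cortical
rh.middletemporal_1	R	cortical
rh.middletemporal_2	R	cortical
rh.middletemporal_3	R	cortical
rh.paracentral_1	R	cortical
rh.paracentral_2	R	cortical
rh.paracentral_3	R	cortical
rh.parahippocampal_1	R	cortical
rh.parahippocampal_2	R	cortical
rh.parahippocampal_3	R	cortical
rh.parsopercularis_1	R	cortical
rh.parsopercularis_2	R	cortical
rh.parsopercularis_3	R	cortical
rh.parsorbitalis_1	R	cortical
rh.parsorbitalis_2	R	cortical
rh.parsorbitalis_3	R	cortical
rh.parstriangularis_1	R	cortical
rh.parstriangularis_2	R	cortical
rh.parstriangularis_3	R	cortical
rh.pericalcarine_1	R	cortical
rh.pericalcarine_2	R	cortical
rh.pericalcarine_3	R	cortical
rh.postcentral_1	R	cortical
rh.postcentral_2	R	cortical
rh.postcentral_3	R	cortical
rh.posteriorcingulate_1	R	cortical
rh.posteriorcingulate_2	R	cortical
rh.posteriorcingulate_3	R	cortical
rh.precentral_1	R	cortical
rh.precentral_2	R	cortical
rh.precentral_3	R	cortical
rh.precuneus_1	R	cortical
rh.precuneus_2	R	cortical
rh.precuneus_3	R	cortical
rh.rostralanteriorcingulate_1	R	cortical
rh.rostralanteriorcingulate_2	R	cortical
rh.rostralanteriorcingulate_3	R	cortical
rh.rostralmiddlefrontal_1	R	cortical
rh.rostralmiddlefrontal_2	R	cortical
rh.rostralmiddlefrontal_3	R	cortical
rh.superiorfrontal_1	R	cortical
rh.superiorfrontal_2	R	cortical
rh.superiorfrontal_3	R	cortical
rh.superiorparietal_1	R	cortical
rh.superiorparietal_2	R	cortical
rh.superiorparietal_3	R	cortical
rh.superiortemporal_1	R	cortical
rh.superiortemporal_2	R	cortical
rh.superiortemporal_3	R	cortical
rh.supramarginal_1	R	cortical
rh.supramarginal_2	R	cortical
rh.supramarginal_3	R	cortical
rh.temporalpole_1	R	cortical
rh.temporalpole_2	R	cortical
rh.temporalpole_3	R	cortical
rh.transversetemporal_1	R	cortical
rh.transversetemporal_2	R	cortical
rh.transversetemporal_3	R	cortical
lh.thalamus	L	subcortical
lh.caudate	L	subcortical
lh.putamen	L	subcortical
lh.pallidum	L	subcortical
lh.accumbens	L	subcortical
lh.hippocampus	L	subcortical
lh.amygdala	L	subcortical
rh.thalamus	R	subcortical
rh.caudate	R	subcortical
rh.putamen	R	subcortical
rh.pallidum	R	subcortical
rh.accumbens	R	subcortical
rh.hippocampus	R	subcortical
rh.amygdala	R	subcortical
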
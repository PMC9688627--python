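region,electrodes
Transverse temporal,TP8;T7;T8
Banks superior temporal sulcus,P8;TP7;TP8
Caudal anterior-cingulate,FC2;AFz;F2
Caudal middle frontal,FC6;FC3;FC4
Isthmus-cingulate,PO8;PO7;Pz;POz
Lateral occipital,PO7;PO8;O1;O2
Lateral orbitofrontal,N2;F8;N1;F9;F10
Lingual gyrus,Iz;PO8;PO7;Oz
Medial orbital frontal,Fp2;N2;Fpz
Paracentral lobule,C1;C2;Cpz;Cz
Pars opercularis,FC5;FC6;FT7;FT8
Pars orbitalis,F8;AF7;F9;F10
Pars triangularis,FT7;FT8;F5;F8;F7
Pericalcarine,POz;O1;O2;Oz
Postcentral gyrus,T8;C5;C4;C6;C3
Posterior cingulate,Cz;C1;FC2;C2
Precentral gyrus,C3;C2;C4;C1
Precuneus,PO3;Pz;POz
Rostral anterior cingulate,AF4;AFz;Fp2;Fpz
Rostral middle frontal gyrus,AF3;F5;AF8;F6
Superior frontal gyrus,AF3;F5;AF8;F6
Superior parietal,POz;CP1;P2;P1
Superior temporal gyrus,TP8;FT9;T8;T7
Supramarginal gyrus,C5;CP5;CP6
Cuneus,PO3;PO4;Oz;POz
Inferior parietal,P3;P4;P5;P6
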
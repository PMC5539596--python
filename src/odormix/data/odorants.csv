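name,abbreviation,cas,odor_threshold_mg_m3,family
Acetaldehyde,A,75-07-0,0.039,aldehydes
Propionaldehyde,P,123-38-6,0.041,aldehydes
n-Butyraldehyde,B,123-72-8,0.052,aldehydes
Ethyl acetate,EA,141-78-6,0.276,esters
Butyl acetate,BA,123-86-4,0.085,esters
Ethyl butyrate,EB,105-54-4,0.053,esters
n-Butyl acrylate,NBA,141-32-2,0.038,esters
Vinyl acetate,VA,108-05-4,0.072,esters
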
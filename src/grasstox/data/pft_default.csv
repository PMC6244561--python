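species,size_class,growth_form,resource_response,grazing_response,alloc_shoot,alloc_root
B. erectus,large,semi-rosette,stress-tolerator,tolerator,0,0
C. cristatus,large,semi-rosette,intermediate,avoider,0,0
G. mollugo,medium,erect,competitor,intermediate,0,0
L. hispidus,medium,rosette,intermediate,tolerator,0,0
S. nutans,medium,semi-rosette,intermediate,intermediate,0,0.5
T. pratense,medium,semi-rosette,competitor,tolerator,0.2,0
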
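drug,action,threshold_ml_min,classes,source
metoclopramide,avoid,40,,28
famotidine,reduce_dose,50,,27|28
ranitidine,reduce_dose,50,,27|28
metformin,avoid,60,,28
acarbose,avoid,25,,9
gliclazide,reduce_dose,50,,9
dabigatran,avoid,30,,27
rivaroxaban,reduce_dose,50,,27
rivaroxaban,avoid,30,,27
enoxaparin,reduce_dose,30,,27
digoxin,reduce_dose,50,,9
sotalol,avoid,40,,28
atenolol,reduce_dose,35,,28
amiloride,avoid,30,diuretic|potassium_sparing_diuretic,27
spironolactone,avoid,30,diuretic|aldosterone_antagonist|potassium_sparing_diuretic,27
hydrochlorothiazide,avoid,30,diuretic,27
rosuvastatin,reduce_dose,60,,9
fenofibrate,reduce_dose,60,,9
tramadol,reduce_dose,30,,27
morphine,reduce_dose,50,,9
oxycodone,reduce_dose,50,,9
nsaids,avoid,50,nsaid,9
duloxetine,avoid,30,,27
bupropion,reduce_dose,50,,9
venlafaxine,reduce_dose,30,,9
gabapentin,reduce_dose,60,,27|28
pregabalin,reduce_dose,60,,27
levetiracetam,reduce_dose,80,,9|27
topiramate,reduce_dose,70,,27
piracetam,reduce_dose,50,,9
risperidone,reduce_dose,50,,9
sulpiride,reduce_dose,50,,9
cetirizine,reduce_dose,30,,28
fexofenadine,reduce_dose,80,,28
tizanidine,reduce_dose,25,,9
colchicine,reduce_dose,30,,27
alendronic acid,avoid,35,,9
methotrexate,reduce_dose,50,,9
memantine,reduce_dose,30,,9|28
ramipril,,,acei,class-list
enalapril,,,acei,class-list
perindopril,,,acei,class-list
lisinopril,,,acei,class-list
captopril,,,acei,class-list
quinapril,,,acei,class-list
cilazapril,,,acei,class-list
trandolapril,,,acei,class-list
losartan,,,arb,class-list
valsartan,,,arb,class-list
telmisartan,,,arb,class-list
candesartan,,,arb,class-list
irbesartan,,,arb,class-list
furosemide,,,diuretic,class-list
torasemide,,,diuretic,class-list
indapamide,,,diuretic,class-list
chlortalidone,,,diuretic,class-list
eplerenone,,,aldosterone_antagonist,class-list
triamterene,,,potassium_sparing_diuretic,class-list
potassium chloride,,,potassium_containing_agent,class-list
potassium citrate,,,potassium_containing_agent,class-list
ibuprofen,,,nsaid,class-list
diclofenac,,,nsaid,class-list
naproxen,,,nsaid,class-list
ketoprofen,,,nsaid,class-list
indomethacin,,,nsaid,class-list
piroxicam,,,nsaid,class-list
meloxicam,,,nsaid_meloxicam_nimesulide,class-list
nimesulide,,,nsaid_meloxicam_nimesulide,class-list
aspirin_low_dose,,,other,class-list
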
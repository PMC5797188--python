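landmark,scan1,scan2,scan3,scan4
left antennal nerve,3.0,3.0,0.5,0.7
right antennal nerve,2.6,3.4,0.5,2.9
left tip of vertical lobe,2.6,2.2,1.8,3.8
right tip of vertical lobe,2.2,0.5,1.5,0.5
end of ventral nerve cord,0.5,4.1,2.1,0.7
left thoracic nerve entry T1,2.1,0.6,0.9,2.0
right thoracic nerve entry T1,1.3,0.5,1.3,1.0
left thoracic nerve entry T2,1.0,0.5,1.3,0.7
right thoracic nerve entry T2,3.4,3.9,2.4,1.5
left thoracic nerve entry T3,0.6,0.6,1.0,0.9
right thoracic nerve entry T3,5.6,2.1,1.0,2.3
left upper peduncle,3.1,3.3,2.9,6.2
right upper peduncle,5.6,4.4,2.1,3.6
anterior upper commisure,4.2,1.0,1.5,2.9
posterior upper commisure,0.0,0.6,3.9,2.3
left anterior LON nerve,1.0,2.5,2.0,2.3
right anterior LON nerve,0.6,1.4,4.4,2.3
left MB vertical medial lobe connection,0.5,0.5,0.5,2.9
right MB vertical medial lobe connection,2.4,1.4,2.7,0.5
center SEZ neuropil fusion,1.6,4.3,1.4,1.8
left upper most anterior nerve entry,0.9,2.2,2.4,4.3
right upper most anterior nerve entry,10.0,1.0,2.7,5.4
right basal brain neuropil border posterior,0.5,2.2,1.4,2.1
left basal brain neuropil border posterior,4.2,0.6,4.2,2.3
left A8 nerve entry,0.0,1.8,1.5,4.4
right A8 nerve entry,1.8,1.4,1.0,4.6
right A7 nerve entry,0.0,0.6,1.3,1.0
left A7 nerve entry,1.0,0.5,0.5,1.4
left A6 nerve entry,2.1,0.5,0.5,0.7
right A6 nerve entry,0.5,2.1,0.0,2.8
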
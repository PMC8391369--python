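<?xml version="1.0" encoding="utf-8"?>
<aiml version="subset-1.0">
  <topic name="beginning_conversation" description="saludos de bienvenida al paciente">
    <category role="opening">
      <pattern>INICIO</pattern>
      <template><random>
        <li>¡Hola<condition name="patient_name">, <get name="patient_name"/></condition>! ¿Cómo te encuentras el día de hoy?</li>
        <li>¡Muy buenos días<condition name="patient_name">, <get name="patient_name"/></condition>! ¿Cómo amaneciste hoy?</li>
      </random></template>
    </category>
    <category role="trigger">
      <pattern>HOLA</pattern>
      <template><random>
        <li>¡Hola<condition name="patient_name">, <get name="patient_name"/></condition>! Me da mucho gusto saludarte. ¿Cómo estás?</li>
        <li>¡Hola! ¿Te gustaría platicar un rato conmigo?</li>
      </random></template>
    </category>
    <category role="trigger">
      <pattern>_ HOLA</pattern>
      <template><srai>HOLA</srai></template>
    </category>
    <category role="trigger">
      <pattern>HOLA _</pattern>
      <template><srai>HOLA</srai></template>
    </category>
    <category role="trigger">
      <pattern>_ HOLA _</pattern>
      <template><srai>HOLA</srai></template>
    </category>
    <category role="trigger">
      <pattern>BUENOS DÍAS</pattern>
      <template><srai>HOLA</srai></template>
    </category>
    <category role="trigger">
      <pattern>_ BUENOS DÍAS</pattern>
      <template><srai>HOLA</srai></template>
    </category>
    <category role="trigger">
      <pattern>BUENOS DÍAS _</pattern>
      <template><srai>HOLA</srai></template>
    </category>
    <category role="trigger">
      <pattern>_ BUENOS DÍAS _</pattern>
      <template><srai>HOLA</srai></template>
    </category>
    <category role="trigger">
      <pattern>BUENAS TARDES</pattern>
      <template><srai>HOLA</srai></template>
    </category>
    <category role="trigger">
      <pattern>_ BUENAS TARDES</pattern>
      <template><srai>HOLA</srai></template>
    </category>
    <category role="trigger">
      <pattern>BUENAS TARDES _</pattern>
      <template><srai>HOLA</srai></template>
    </category>
    <category role="trigger">
      <pattern>_ BUENAS TARDES _</pattern>
      <template><srai>HOLA</srai></template>
    </category>
    <category role="trigger">
      <pattern>QUÉ TAL</pattern>
      <template><srai>HOLA</srai></template>
    </category>
    <category role="trigger">
      <pattern>_ QUÉ TAL</pattern>
      <template><srai>HOLA</srai></template>
    </category>
    <category role="trigger">
      <pattern>QUÉ TAL _</pattern>
      <template><srai>HOLA</srai></template>
    </category>
    <category role="trigger">
      <pattern>_ QUÉ TAL _</pattern>
      <template><srai>HOLA</srai></template>
    </category>
    <category>
      <pattern>SÍ</pattern>
      <template><random>
        <li>¡Qué alegría! ¿De qué tema te gustaría platicar?</li>
        <li>¡Muy bien! ¿Quieres que platiquemos de tu familia o de tus pasatiempos?</li>
      </random></template>
    </category>
    <category>
      <pattern>SI</pattern>
      <template><srai>SÍ</srai></template>
    </category>
    <category>
      <pattern>SÍ _</pattern>
      <template><srai>SÍ</srai></template>
    </category>
    <category>
      <pattern>SI _</pattern>
      <template><srai>SÍ</srai></template>
    </category>
    <category>
      <pattern>NO</pattern>
      <template><random>
        <li>Está bien, no hay prisa. ¿Cómo te sientes hoy?</li>
        <li>No te preocupes. ¿Prefieres que platiquemos más tarde?</li>
      </random></template>
    </category>
    <category role="fallback">
      <pattern>*</pattern>
      <template><random>
        <li>Me da gusto escucharte. ¿Cómo ha estado tu día?</li>
        <li>Qué interesante. ¿Me cuentas cómo te sientes hoy?</li>
      </random></template>
    </category>
  </topic>
</aiml>
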